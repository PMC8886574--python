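{
 "label": "Fe(III)/6d (MeOH/H2O 80/20)",
 "components": [
  "Fe",
  "L",
  "H"
 ],
 "solvent": "MeOH/H2O 80/20",
 "pKw": 14.42,
 "temperature_C": 25.0,
 "ionic_strength_M": 0.1,
 "source": "Fe(III) complexation of 1-hydroxy-3-(4-hydroxybenzyl)-5,6-dimethylpyrazin-2(1H)-one (6d) in MeOH/H2O 80/20 w/w, I = 0.1 M NaClO4, 25.0 C; protonated-complex FeLH/FeL2H2/FeL3H3 model (phenol stays protonated) with mixed-solvent Fe(III) hydrolysis species",
 "species": [
  {
   "name": "LH",
   "nM": 0,
   "nL": 1,
   "nH": 1,
   "log_beta": 10.57,
   "approximate": false
  },
  {
   "name": "LH2",
   "nM": 0,
   "nL": 1,
   "nH": 2,
   "log_beta": 16.53,
   "approximate": false
  },
  {
   "name": "LH3",
   "nM": 0,
   "nL": 1,
   "nH": 3,
   "log_beta": 17.470000000000002,
   "approximate": false
  },
  {
   "name": "FeLH",
   "nM": 1,
   "nL": 1,
   "nH": 1,
   "log_beta": 26.7,
   "approximate": false
  },
  {
   "name": "FeL2H2",
   "nM": 1,
   "nL": 2,
   "nH": 2,
   "log_beta": 46.3,
   "approximate": false
  },
  {
   "name": "FeL3H3",
   "nM": 1,
   "nL": 3,
   "nH": 3,
   "log_beta": 62.3,
   "approximate": false
  },
  {
   "name": "Fe(OH)",
   "nM": 1,
   "nL": 0,
   "nH": -1,
   "log_beta": -1.57,
   "approximate": false
  },
  {
   "name": "Fe(OH)2",
   "nM": 1,
   "nL": 0,
   "nH": -2,
   "log_beta": -4.63,
   "approximate": false
  }
 ]
}
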