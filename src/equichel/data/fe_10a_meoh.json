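{
 "label": "Fe(III)/10a (MeOH/H2O 80/20)",
 "components": [
  "Fe",
  "L",
  "H"
 ],
 "solvent": "MeOH/H2O 80/20",
 "pKw": 14.42,
 "temperature_C": 25.0,
 "ionic_strength_M": 0.1,
 "source": "Fe(III) complexation of 1-hydroxy-6-phenylpyrazin-2(1H)-one (10a) in MeOH/H2O 80/20 w/w, I = 0.1 M NaClO4, 25.0 C; FeL/FeL2/FeL3 model with mixed-solvent Fe(III) hydrolysis species",
 "species": [
  {
   "name": "LH",
   "nM": 0,
   "nL": 1,
   "nH": 1,
   "log_beta": 4.24,
   "approximate": false
  },
  {
   "name": "LH2",
   "nM": 0,
   "nL": 1,
   "nH": 2,
   "log_beta": 3.3400000000000003,
   "approximate": true
  },
  {
   "name": "FeL",
   "nM": 1,
   "nL": 1,
   "nH": 0,
   "log_beta": 9.79,
   "approximate": false
  },
  {
   "name": "FeL2",
   "nM": 1,
   "nL": 2,
   "nH": 0,
   "log_beta": 17.89,
   "approximate": false
  },
  {
   "name": "FeL3",
   "nM": 1,
   "nL": 3,
   "nH": 0,
   "log_beta": 21.7,
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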