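{
 "label": "10a protonation (H2O)",
 "components": [
  "Fe",
  "L",
  "H"
 ],
 "solvent": "H2O",
 "pKw": 13.77,
 "temperature_C": 25.0,
 "ionic_strength_M": 0.1,
 "source": "Protonation of 1-hydroxy-6-phenylpyrazin-2(1H)-one (10a) in water, I = 0.1 M NaClO4, 25.0 C (no complexation data in this solvent); aqueous Fe(III) hydrolysis species included for completeness",
 "species": [
  {
   "name": "LH",
   "nM": 0,
   "nL": 1,
   "nH": 1,
   "log_beta": 3.18,
   "approximate": false
  },
  {
   "name": "LH2",
   "nM": 0,
   "nL": 1,
   "nH": 2,
   "log_beta": 2.58,
   "approximate": true
  },
  {
   "name": "Fe(OH)",
   "nM": 1,
   "nL": 0,
   "nH": -1,
   "log_beta": -2.56,
   "approximate": false
  },
  {
   "name": "Fe(OH)2",
   "nM": 1,
   "nL": 0,
   "nH": -2,
   "log_beta": -6.2,
   "approximate": false
  },
  {
   "name": "Fe(OH)3",
   "nM": 1,
   "nL": 0,
   "nH": -3,
   "log_beta": -11.41,
   "approximate": false
  },
  {
   "name": "Fe(OH)4",
   "nM": 1,
   "nL": 0,
   "nH": -4,
   "log_beta": -21.88,
   "approximate": false
  },
  {
   "name": "Fe2(OH)2",
   "nM": 2,
   "nL": 0,
   "nH": -2,
   "log_beta": -2.84,
   "approximate": false
  },
  {
   "name": "Fe3(OH)4",
   "nM": 3,
   "nL": 0,
   "nH": -4,
   "log_beta": -6.05,
   "approximate": false
  }
 ]
}
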