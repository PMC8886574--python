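{
 "label": "Fe(III) hydrolysis (MeOH/H2O 80/20)",
 "components": [
  "Fe",
  "L",
  "H"
 ],
 "solvent": "MeOH/H2O 80/20",
 "pKw": 14.42,
 "temperature_C": 25.0,
 "ionic_strength_M": 0.1,
 "source": "Mixed-solvent Fe(III) hydrolysis species, I = 0.1 M NaClO4, 25.0 C",
 "species": [
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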