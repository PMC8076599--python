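{
 "_schema": "oocyteflux transporter fixtures v1",
 "_note": "Km (uM) / Vmax (pmol/oocyte/h) are fixture constants chosen to reproduce the qualitative substrate profiles; stoichiometry is descriptive metadata only.",
 "transporters": [
  {
   "name": "SNAT2-like",
   "mechanism": "symport",
   "stoichiometry": "1 Na+ : 1 AA",
   "substrates": {
    "Alanine": [
     300,
     200
    ],
    "Serine": [
     300,
     180
    ],
    "Glycine": [
     400,
     160
    ],
    "Proline": [
     500,
     300
    ],
    "Methionine": [
     350,
     250
    ],
    "Asparagine": [
     350,
     250
    ],
    "Glutamine": [
     400,
     400
    ],
    "Threonine": [
     450,
     120
    ],
    "Leucine": [
     800,
     120
    ],
    "Histidine": [
     600,
     120
    ]
   }
  },
  {
   "name": "SNAT1-like",
   "mechanism": "symport",
   "stoichiometry": "1 Na+ : 1 AA",
   "substrates": {
    "Alanine": [
     300,
     200
    ],
    "Serine": [
     300,
     180
    ],
    "Glycine": [
     400,
     160
    ],
    "Methionine": [
     350,
     250
    ],
    "Asparagine": [
     350,
     250
    ],
    "Glutamine": [
     400,
     400
    ],
    "Threonine": [
     450,
     120
    ],
    "Histidine": [
     600,
     120
    ]
   }
  },
  {
   "name": "B0AT1-like",
   "mechanism": "symport",
   "stoichiometry": "1 Na+ : 1 AA",
   "substrates": {
    "Alanine": [
     600,
     150
    ],
    "Serine": [
     600,
     250
    ],
    "Glycine": [
     700,
     120
    ],
    "Proline": [
     900,
     500
    ],
    "Methionine": [
     400,
     250
    ],
    "Asparagine": [
     600,
     400
    ],
    "Glutamine": [
     500,
     400
    ],
    "Threonine": [
     600,
     140
    ],
    "Leucine": [
     300,
     220
    ],
    "Isoleucine": [
     300,
     220
    ],
    "Valine": [
     350,
     200
    ],
    "Phenylalanine": [
     400,
     180
    ],
    "Tyrosine": [
     500,
     250
    ],
    "Cysteine": [
     700,
     200
    ],
    "Histidine": [
     900,
     200
    ],
    "Tryptophan": [
     5000,
     60
    ]
   }
  },
  {
   "name": "EAAT1-like",
   "mechanism": "symport",
   "stoichiometry": "3 Na+/1 H+ : 1 AA- (1 K+ counter)",
   "substrates": {
    "Glutamic acid": [
     30,
     30
    ],
    "Aspartic acid": [
     30,
     30
    ]
   }
  },
  {
   "name": "LAT1-like",
   "mechanism": "antiport",
   "stoichiometry": "1 AA : 1 AA obligatory exchange",
   "substrates": {
    "Isoleucine": [
     50,
     200
    ],
    "Leucine": [
     50,
     200
    ],
    "Phenylalanine": [
     40,
     200
    ],
    "Tryptophan": [
     40,
     200
    ],
    "Tyrosine": [
     60,
     200
    ],
    "Histidine": [
     150,
     200
    ],
    "Methionine": [
     80,
     200
    ],
    "Valine": [
     200,
     200
    ],
    "Glutamine": [
     500,
     200
    ]
   }
  },
  {
   "name": "ASCT2-like",
   "mechanism": "antiport",
   "stoichiometry": "1 AA : 1 AA obligatory exchange (Na+ dependent)",
   "substrates": {
    "Alanine": [
     80,
     200
    ],
    "Serine": [
     80,
     200
    ],
    "Threonine": [
     100,
     200
    ],
    "Cysteine": [
     150,
     200
    ],
    "Glutamine": [
     70,
     200
    ],
    "Asparagine": [
     90,
     200
    ],
    "Methionine": [
     300,
     200
    ],
    "Glutamic acid": [
     3000,
     200
    ]
   }
  },
  {
   "name": "uninjected",
   "mechanism": "none",
   "stoichiometry": "",
   "substrates": {}
  }
 ]
}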