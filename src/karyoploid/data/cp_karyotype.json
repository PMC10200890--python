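{
 "chromosomes": [
  {
   "name": "Cp1",
   "tokens": [
    "D+@1",
    "CEN",
    "E+@1"
   ]
  },
  {
   "name": "Cp2",
   "tokens": [
    "D+@2",
    "CEN",
    "E+@2"
   ]
  },
  {
   "name": "Cp3",
   "tokens": [
    "F+@1",
    "CEN",
    "G+@1",
    "H+@1"
   ]
  },
  {
   "name": "Cp4",
   "tokens": [
    "I+@1",
    "CEN",
    "J+@1"
   ]
  },
  {
   "name": "Cp5",
   "tokens": [
    "I+@2",
    "CEN",
    "J+@2"
   ]
  },
  {
   "name": "Cp6",
   "tokens": [
    "(K-L)+@1",
    "CEN",
    "(M-N)+@1"
   ]
  },
  {
   "name": "Cp7",
   "tokens": [
    "O+@1",
    "P+@1",
    "CEN",
    "Q+@1",
    "R+@1"
   ]
  },
  {
   "name": "Cp8",
   "tokens": [
    "S+@1",
    "T+@1",
    "CEN",
    "U+@1"
   ]
  },
  {
   "name": "Cp9",
   "tokens": [
    "V+@1",
    "CEN",
    "W+@1",
    "X+@1"
   ]
  },
  {
   "name": "Cp10",
   "tokens": [
    "V+@2",
    "CEN",
    "W+@2",
    "X+@2"
   ]
  },
  {
   "history": [
    "centromere of AK7b eliminated"
   ],
   "name": "Cp15",
   "tokens": [
    "Fa+@2",
    "T-@2",
    "S-@2",
    "(K-L)+@2",
    "CEN",
    "(M-N)+@2"
   ]
  },
  {
   "name": "Cp14",
   "tokens": [
    "U-@2",
    "Fb+@2",
    "Ha-@2",
    "G-@2",
    "CEN",
    "Fc-@2",
    "Hb+@2"
   ]
  },
  {
   "name": "Cp11",
   "tokens": [
    "Aa+@1",
    "Ca-@1",
    "CEN",
    "B-@1",
    "Ab-@1",
    "Cb+@1"
   ]
  },
  {
   "name": "Cp12",
   "tokens": [
    "Ab+@2",
    "B+@2",
    "CEN",
    "C+@2"
   ]
  },
  {
   "name": "Cp13",
   "tokens": [
    "Aa+@2",
    "O+@2",
    "P+@2",
    "CEN",
    "Q+@2",
    "R+@2"
   ]
  }
 ],
 "cuts": {
  "A@1": [
   0.5
  ],
  "A@2": [
   0.5
  ],
  "C@1": [
   0.5
  ],
  "F@2": [
   0.5,
   0.75
  ],
  "H@2": [
   0.5
  ]
 },
 "format": "karyoploid-karyotype/1"
}
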