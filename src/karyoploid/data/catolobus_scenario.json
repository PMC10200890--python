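{
 "events": [
  {
   "annotation": "",
   "kind": "WGD",
   "params": {}
  },
  {
   "annotation": "fusion U+T+S+(K-L)+(M-N); AK7 centromere eliminated/inactivated",
   "kind": "EET",
   "params": {
    "chr_a": "AK7b",
    "chr_b": "AK5b",
    "end_a": "head",
    "end_b": "head",
    "keep_centromere_of": "AK5b",
    "name": "AK5/7b"
   }
  },
  {
   "annotation": "products Cp15 [Fa+T+S+(K-L)+(M-N)] and U+Fb+G+H",
   "kind": "RECIP_TRANSLOC",
   "params": {
    "bp1": {
     "block": "F",
     "chrom": "AK3b",
     "coord": 0.5
    },
    "bp2": {
     "block": "T",
     "chrom": "AK5/7b",
     "coord": 1.0
    },
    "names": [
     "U+Fb+G+H",
     "Cp15"
    ]
   }
  },
  {
   "annotation": "8.21-Mb pericentric inversion; breakpoints in Fb between AT3G60970 (MRP15) and AT3G14220 (MLE3), and in H between AT2G18900 (F19F24) and AT2G19000 (T20K24)",
   "kind": "PERI_INV",
   "params": {
    "bp_left": {
     "block": "F",
     "chrom": "U+Fb+G+H",
     "coord": 0.75
    },
    "bp_right": {
     "block": "H",
     "chrom": "U+Fb+G+H",
     "coord": 0.5
    },
    "chrom": "U+Fb+G+H",
    "name": "Cp14"
   }
  },
  {
   "annotation": "15.2-Mb pericentric inversion; breakpoints in A between AT1G12180 (T28K15) and AT1G12660 (T12C24), and in C between AT1G52240 (F9I5) and AT1G52450 (F6D8)",
   "kind": "PERI_INV",
   "params": {
    "bp_left": {
     "block": "A",
     "chrom": "AK1a",
     "coord": 0.5
    },
    "bp_right": {
     "block": "C",
     "chrom": "AK1a",
     "coord": 0.5
    },
    "chrom": "AK1a",
    "name": "Cp11"
   }
  },
  {
   "annotation": "unequal reciprocal translocation; breakpoint in A between AT1G13500 (F13B4) and AT1G14220 (F7A19), to the subtelomeric region of the AK6 upper arm",
   "kind": "UNEQ_TRANSLOC",
   "params": {
    "bp": {
     "block": "A",
     "chrom": "AK1b",
     "coord": 0.5
    },
    "names": [
     "Cp12",
     "Cp13"
    ],
    "target_chr": "AK6b",
    "target_end": "head"
   }
  }
 ],
 "format": "karyoploid-scenario/1",
 "rename": {
  "AK2a": "Cp1",
  "AK2b": "Cp2",
  "AK3a": "Cp3",
  "AK4a": "Cp4",
  "AK4b": "Cp5",
  "AK5a": "Cp6",
  "AK6a": "Cp7",
  "AK7a": "Cp8",
  "AK8a": "Cp9",
  "AK8b": "Cp10"
 },
 "start": "ACK"
}
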