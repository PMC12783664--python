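{
 "name": "canonical-39",
 "image_size": 64,
 "scale": 4,
 "groups": [
  {
   "group_id": "DOT",
   "variant_angles": [
    0
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000001111000000",
    "0000001111000000",
    "0000001111000000",
    "0000001111000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "PP",
   "variant_angles": [
    0,
    90,
    180
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0011100000000000",
    "0011100000000000",
    "0011100000000000",
    "0000000000000000",
    "0000000000011100",
    "0000000000011100",
    "0000000000011100",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "D",
   "variant_angles": [
    0,
    90
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0011111111111100",
    "0011111111111100",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "E",
   "variant_angles": [
    0,
    90,
    180,
    270
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0001111111111000",
    "0001111111111000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001111111100000",
    "0001111111100000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001111111111000",
    "0001111111111000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "H",
   "variant_angles": [
    0,
    90
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001111111111000",
    "0001111111111000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "L",
   "variant_angles": [
    0,
    90,
    180,
    270
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001111111110000",
    "0001111111110000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "T",
   "variant_angles": [
    0,
    90,
    180,
    270
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0011111111111100",
    "0011111111111100",
    "0000000110000000",
    "0000000110000000",
    "0000000110000000",
    "0000000110000000",
    "0000000110000000",
    "0000000110000000",
    "0000000110000000",
    "0000000110000000",
    "0000000110000000",
    "0000000110000000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "F",
   "variant_angles": [
    0,
    90,
    180,
    270
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0001111111111000",
    "0001111111111000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001111111100000",
    "0001111111100000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "U",
   "variant_angles": [
    0,
    90,
    180,
    270
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001100000011000",
    "0001111111111000",
    "0001111111111000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "J",
   "variant_angles": [
    0,
    90,
    180,
    270
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0000000001100000",
    "0000000001100000",
    "0000000001100000",
    "0000000001100000",
    "0000000001100000",
    "0000000001100000",
    "0000000001100000",
    "0000000001100000",
    "0000000001100000",
    "0000000001100000",
    "0001111111100000",
    "0001111111100000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "P",
   "variant_angles": [
    0,
    90,
    180,
    270
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0001111111110000",
    "0001111111110000",
    "0001100000110000",
    "0001100000110000",
    "0001111111110000",
    "0001111111110000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0000000000000000",
    "0000000000000000"
   ]
  },
  {
   "group_id": "C",
   "variant_angles": [
    0,
    90,
    180
   ],
   "bitmap": [
    "0000000000000000",
    "0000000000000000",
    "0001111111111000",
    "0001111111111000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001100000000000",
    "0001111111111000",
    "0001111111111000",
    "0000000000000000",
    "0000000000000000"
   ]
  }
 ]
}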