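{
 "format": "hamartini-ff",
 "version": "1.0",
 "sha256": "c9e0d9434df5db52bf9ba4505f0729c02f7a8f5257491cdb38fb9fff729aebea",
 "payload": {
  "beads": [
   [
    1,
    "T1",
    "P3r",
    "T",
    0,
    "hydroxymethyl group of GlcNAc"
   ],
   [
    2,
    "T2",
    "N4r",
    "T",
    0,
    "ring oxygen + anomeric carbon of GlcNAc"
   ],
   [
    3,
    "R3",
    "P2r",
    "R",
    0,
    "ethanolamine group of GlcNAc"
   ],
   [
    4,
    "S4",
    "N4r",
    "S",
    0,
    "hydroxyethyl group of GlcNAc"
   ],
   [
    5,
    "S5",
    "N5ar",
    "S",
    0,
    "N-acetyl group of GlcNAc"
   ],
   [
    6,
    "S6",
    "Q5n",
    "S",
    -1,
    "carboxylate group of GlcA"
   ],
   [
    7,
    "T7",
    "N4r",
    "T",
    0,
    "ring oxygen + anomeric carbon of GlcA"
   ],
   [
    8,
    "R8",
    "P3r",
    "R",
    0,
    "vicinal diol of GlcA"
   ],
   [
    9,
    "S9",
    "N4r",
    "S",
    0,
    "oxyethyl group of GlcA"
   ]
  ],
  "reducing_end_grows": {
   "GlcNAc": 2,
   "GlcA": 7
  },
  "residue_beads": {
   "GlcNAc": [
    1,
    2,
    3,
    4,
    5
   ],
   "GlcA": [
    6,
    7,
    8,
    9
   ]
  },
  "masses": {
   "R": 72.0,
   "S": 54.0,
   "T": 36.0
  },
  "monomers": {
   "GlcNAc": {
    "bonds": [
     [
      1,
      4,
      10700,
      0.27
     ],
     [
      2,
      3,
      19000,
      0.284
     ],
     [
      2,
      4,
      25000,
      0.354
     ],
     [
      3,
      4,
      19000,
      0.288
     ],
     [
      3,
      5,
      9500,
      0.327
     ],
     [
      4,
      5,
      10500,
      0.631
     ]
    ],
    "angles": [
     [
      1,
      4,
      2,
      230,
      81,
      "g96"
     ],
     [
      1,
      4,
      3,
      220,
      134,
      "g96"
     ],
     [
      5,
      3,
      2,
      200,
      101,
      "g96"
     ]
    ],
    "impropers": [
     [
      4,
      3,
      2,
      1,
      170,
      7.5
     ],
     [
      3,
      4,
      2,
      5,
      230,
      -3.5
     ]
    ],
    "dihedrals": []
   },
   "GlcA": {
    "bonds": [
     [
      6,
      9,
      14000,
      0.25
     ],
     [
      7,
      8,
      18000,
      0.295
     ],
     [
      7,
      9,
      24000,
      0.357
     ],
     [
      8,
      9,
      18000,
      0.296
     ]
    ],
    "angles": [
     [
      6,
      9,
      7,
      420,
      86,
      "g96"
     ],
     [
      6,
      9,
      8,
      250,
      137,
      "g96"
     ]
    ],
    "impropers": [
     [
      9,
      8,
      7,
      6,
      300,
      10.5
     ]
    ],
    "dihedrals": []
   }
  },
  "dimer_template": {
   "intra": {
    "bonds": [
     [
      1,
      4,
      11700,
      0.274
     ],
     [
      6,
      9,
      65000,
      0.233
     ],
     [
      2,
      3,
      73000,
      0.232
     ],
     [
      7,
      8,
      26000,
      0.261
     ],
     [
      2,
      4,
      36000,
      0.289
     ],
     [
      7,
      9,
      50000,
      0.257
     ],
     [
      3,
      4,
      42000,
      0.284
     ],
     [
      8,
      9,
      28000,
      0.278
     ],
     [
      3,
      5,
      38000,
      0.33
     ],
     [
      2,
      9,
      20000,
      0.255
     ],
     [
      4,
      5,
      3000,
      0.615
     ],
     [
      4,
      7,
      10000,
      0.799
     ]
    ],
    "angles": [
     [
      1,
      4,
      2,
      345,
      78,
      "g96"
     ],
     [
      6,
      9,
      7,
      630,
      93,
      "g96"
     ],
     [
      1,
      4,
      3,
      270,
      126,
      "g96"
     ],
     [
      6,
      9,
      8,
      345,
      146,
      "restricted"
     ],
     [
      5,
      3,
      2,
      500,
      126,
      "g96"
     ],
     [
      3,
      2,
      9,
      150,
      93,
      "g96"
     ],
     [
      2,
      9,
      8,
      150,
      116,
      "g96"
     ],
     [
      2,
      9,
      6,
      150,
      80,
      "g96"
     ]
    ],
    "impropers": [
     [
      4,
      3,
      2,
      1,
      150,
      16
     ],
     [
      5,
      3,
      2,
      4,
      170,
      -173
     ],
     [
      9,
      8,
      7,
      6,
      350,
      13
     ],
     [
      2,
      3,
      9,
      4,
      170,
      5
     ],
     [
      9,
      2,
      8,
      7,
      300,
      13
     ]
    ],
    "dihedrals": [
     [
      1,
      3,
      8,
      6,
      -32,
      -138,
      1
     ]
    ]
   },
   "junction": {
    "bonds": [
     [
      7,
      12,
      400,
      0.292
     ],
     [
      7,
      11,
      5000,
      0.473
     ],
     [
      9,
      13,
      4000,
      0.573
     ],
     [
      2,
      12,
      5000,
      0.802
     ]
    ],
    "angles": [
     [
      8,
      7,
      12,
      250,
      110,
      "g96"
     ],
     [
      7,
      12,
      11,
      200,
      120,
      "g96"
     ],
     [
      7,
      12,
      13,
      150,
      66,
      "g96"
     ]
    ],
    "impropers": [
     [
      7,
      8,
      9,
      12,
      500,
      1
     ],
     [
      12,
      11,
      13,
      7,
      400,
      -18
     ]
    ],
    "dihedrals": [
     [
      8,
      7,
      12,
      11,
      -60,
      -165,
      1
     ]
    ]
   }
  },
  "nonbonded": {
   "exclusion_depth": 1,
   "eps_r": 15.0,
   "cutoff": 1.1,
   "pair_table_source": "martini3"
  },
  "sasa_radii": {
   "T": 0.191,
   "S": 0.23,
   "R": 0.264
  },
  "recommended_timestep": {
   "chain": 0.01,
   "monomer": 0.03
  }
 }
}
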