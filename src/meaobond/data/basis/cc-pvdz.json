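{
 "H": [
  {
   "l": 0,
   "exp": [
    13.01,
    1.962,
    0.4446
   ],
   "coef": [
    0.019685,
    0.137977,
    0.478148
   ]
  },
  {
   "l": 0,
   "exp": [
    0.122
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.727
   ],
   "coef": [
    1.0
   ]
  }
 ],
 "He": [
  {
   "l": 0,
   "exp": [
    38.36,
    5.77,
    1.24
   ],
   "coef": [
    0.023809,
    0.154891,
    0.469987
   ]
  },
  {
   "l": 0,
   "exp": [
    0.2976
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    1.275
   ],
   "coef": [
    1.0
   ]
  }
 ],
 "Li": [
  {
   "l": 0,
   "exp": [
    1469.0,
    220.5,
    50.26,
    14.24,
    4.581,
    1.58,
    0.564,
    0.07345
   ],
   "coef": [
    0.000766,
    0.005892,
    0.029671,
    0.10918,
    0.282789,
    0.453123,
    0.274774,
    0.009751
   ]
  },
  {
   "l": 0,
   "exp": [
    1469.0,
    220.5,
    50.26,
    14.24,
    4.581,
    1.58,
    0.564,
    0.07345
   ],
   "coef": [
    -0.00012,
    -0.000923,
    -0.004689,
    -0.017682,
    -0.048902,
    -0.096009,
    -0.13638,
    0.575102
   ]
  },
  {
   "l": 0,
   "exp": [
    0.02805
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    1.534,
    0.2749,
    0.07362
   ],
   "coef": [
    0.022784,
    0.139107,
    0.500375
   ]
  },
  {
   "l": 1,
   "exp": [
    0.02403
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    0.1239
   ],
   "coef": [
    1.0
   ]
  }
 ],
 "B": [
  {
   "l": 0,
   "exp": [
    4570.0,
    685.9,
    156.5,
    44.47,
    14.48,
    5.131,
    1.898,
    0.3329
   ],
   "coef": [
    0.000696,
    0.005353,
    0.027134,
    0.10138,
    0.272055,
    0.448403,
    0.290123,
    0.014322
   ]
  },
  {
   "l": 0,
   "exp": [
    4570.0,
    685.9,
    156.5,
    44.47,
    14.48,
    5.131,
    1.898,
    0.3329
   ],
   "coef": [
    -0.000139,
    -0.001097,
    -0.005444,
    -0.021916,
    -0.059751,
    -0.138732,
    -0.131482,
    0.539526
   ]
  },
  {
   "l": 0,
   "exp": [
    0.1043
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    6.001,
    1.241,
    0.3364
   ],
   "coef": [
    0.035481,
    0.198072,
    0.50523
   ]
  },
  {
   "l": 1,
   "exp": [
    0.09538
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    0.343
   ],
   "coef": [
    1.0
   ]
  }
 ],
 "C": [
  {
   "l": 0,
   "exp": [
    6665.0,
    1000.0,
    228.0,
    64.71,
    21.06,
    7.495,
    2.797,
    0.5215
   ],
   "coef": [
    0.000692,
    0.005329,
    0.027077,
    0.101718,
    0.27474,
    0.448564,
    0.285074,
    0.015204
   ]
  },
  {
   "l": 0,
   "exp": [
    6665.0,
    1000.0,
    228.0,
    64.71,
    21.06,
    7.495,
    2.797,
    0.5215
   ],
   "coef": [
    -0.000146,
    -0.001154,
    -0.005725,
    -0.023312,
    -0.063955,
    -0.149981,
    -0.127262,
    0.544529
   ]
  },
  {
   "l": 0,
   "exp": [
    0.1596
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    9.439,
    2.002,
    0.5456
   ],
   "coef": [
    0.038109,
    0.20948,
    0.508557
   ]
  },
  {
   "l": 1,
   "exp": [
    0.1517
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    0.55
   ],
   "coef": [
    1.0
   ]
  }
 ],
 "N": [
  {
   "l": 0,
   "exp": [
    9046.0,
    1357.0,
    309.3,
    87.73,
    28.56,
    10.21,
    3.838,
    0.7466
   ],
   "coef": [
    0.0007,
    0.005389,
    0.027406,
    0.103207,
    0.278723,
    0.44854,
    0.278238,
    0.01544
   ]
  },
  {
   "l": 0,
   "exp": [
    9046.0,
    1357.0,
    309.3,
    87.73,
    28.56,
    10.21,
    3.838,
    0.7466
   ],
   "coef": [
    -0.000153,
    -0.001208,
    -0.005992,
    -0.024544,
    -0.067459,
    -0.158078,
    -0.121831,
    0.549003
   ]
  },
  {
   "l": 0,
   "exp": [
    0.2248
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    13.55,
    2.917,
    0.7973
   ],
   "coef": [
    0.039919,
    0.217169,
    0.510319
   ]
  },
  {
   "l": 1,
   "exp": [
    0.2185
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    0.817
   ],
   "coef": [
    1.0
   ]
  }
 ],
 "O": [
  {
   "l": 0,
   "exp": [
    11720.0,
    1759.0,
    400.8,
    113.7,
    37.03,
    13.27,
    5.025,
    1.013
   ],
   "coef": [
    0.00071,
    0.00547,
    0.027837,
    0.1048,
    0.283062,
    0.448719,
    0.270952,
    0.015458
   ]
  },
  {
   "l": 0,
   "exp": [
    11720.0,
    1759.0,
    400.8,
    113.7,
    37.03,
    13.27,
    5.025,
    1.013
   ],
   "coef": [
    -0.00016,
    -0.001263,
    -0.006267,
    -0.025716,
    -0.070924,
    -0.165411,
    -0.116955,
    0.557368
   ]
  },
  {
   "l": 0,
   "exp": [
    0.3023
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    17.7,
    3.854,
    1.046
   ],
   "coef": [
    0.043018,
    0.228913,
    0.508728
   ]
  },
  {
   "l": 1,
   "exp": [
    0.2753
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    1.185
   ],
   "coef": [
    1.0
   ]
  }
 ],
 "F": [
  {
   "l": 0,
   "exp": [
    14710.0,
    2207.0,
    502.8,
    142.6,
    46.47,
    16.7,
    6.356,
    1.316
   ],
   "coef": [
    0.000721,
    0.005553,
    0.028267,
    0.106444,
    0.286814,
    0.448641,
    0.264761,
    0.015333
   ]
  },
  {
   "l": 0,
   "exp": [
    14710.0,
    2207.0,
    502.8,
    142.6,
    46.47,
    16.7,
    6.356,
    1.316
   ],
   "coef": [
    -0.000165,
    -0.001308,
    -0.006495,
    -0.026691,
    -0.07369,
    -0.170776,
    -0.112327,
    0.562814
   ]
  },
  {
   "l": 0,
   "exp": [
    0.3897
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    22.67,
    4.977,
    1.347
   ],
   "coef": [
    0.044878,
    0.235718,
    0.508521
   ]
  },
  {
   "l": 1,
   "exp": [
    0.3471
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    1.64
   ],
   "coef": [
    1.0
   ]
  }
 ]
}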