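{
 "H": [
  {
   "l": 0,
   "exp": [
    33.87,
    5.095,
    1.159,
    0.3258,
    0.1027
   ],
   "coef": [
    0.006068,
    0.045308,
    0.202822,
    0.503903,
    0.383421
   ]
  }
 ],
 "He": [
  {
   "l": 0,
   "exp": [
    234,
    35.16,
    7.989,
    2.212,
    0.6669,
    0.2089
   ],
   "coef": [
    0.002587,
    0.019533,
    0.090998,
    0.27205,
    0.478065,
    0.307737
   ]
  }
 ],
 "Li": [
  {
   "l": 0,
   "exp": [
    5988,
    898.9,
    205.9,
    59.24,
    19.87,
    7.406,
    2.93,
    1.189,
    0.4798,
    0.07509,
    0.02832
   ],
   "coef": [
    0.000133,
    0.001025,
    0.005272,
    0.020929,
    0.06634,
    0.165775,
    0.315038,
    0.393523,
    0.19087,
    0.005414,
    -0.001328
   ]
  },
  {
   "l": 0,
   "exp": [
    5988,
    898.9,
    205.9,
    59.24,
    19.87,
    7.406,
    2.93,
    1.189,
    0.4798,
    0.07509,
    0.02832
   ],
   "coef": [
    -2.1e-05,
    -0.000161,
    -0.00082,
    -0.003326,
    -0.010519,
    -0.028097,
    -0.055936,
    -0.099237,
    -0.112189,
    0.567889,
    0.530382
   ]
  }
 ],
 "B": [
  {
   "l": 0,
   "exp": [
    5473,
    820.9,
    186.8,
    52.83,
    17.08,
    5.999,
    2.208,
    0.5879,
    0.2415,
    0.0861
   ],
   "coef": [
    0.000555,
    0.004291,
    0.021949,
    0.084441,
    0.238557,
    0.435072,
    0.341955,
    0.036856,
    -0.009545,
    0.002368
   ]
  },
  {
   "l": 0,
   "exp": [
    5473,
    820.9,
    186.8,
    52.83,
    17.08,
    5.999,
    2.208,
    0.5879,
    0.2415,
    0.0861
   ],
   "coef": [
    -0.000112,
    -0.000868,
    -0.004484,
    -0.017683,
    -0.053639,
    -0.119005,
    -0.165824,
    0.120107,
    0.595981,
    0.411021
   ]
  },
  {
   "l": 1,
   "exp": [
    12.05,
    2.613,
    0.7475,
    0.2385,
    0.07698
   ],
   "coef": [
    0.013118,
    0.079896,
    0.277275,
    0.50427,
    0.35368
   ]
  }
 ],
 "C": [
  {
   "l": 0,
   "exp": [
    8236,
    1235,
    280.8,
    79.27,
    25.59,
    8.997,
    3.319,
    0.9059,
    0.3643,
    0.1285
   ],
   "coef": [
    0.000531,
    0.004108,
    0.021087,
    0.081853,
    0.234817,
    0.434401,
    0.346129,
    0.039378,
    -0.008983,
    0.002385
   ]
  },
  {
   "l": 0,
   "exp": [
    8236,
    1235,
    280.8,
    79.27,
    25.59,
    8.997,
    3.319,
    0.9059,
    0.3643,
    0.1285
   ],
   "coef": [
    -0.000113,
    -0.000878,
    -0.00454,
    -0.018133,
    -0.05576,
    -0.126895,
    -0.170352,
    0.140382,
    0.598684,
    0.395389
   ]
  },
  {
   "l": 1,
   "exp": [
    18.71,
    4.133,
    1.2,
    0.3827,
    0.1209
   ],
   "coef": [
    0.014031,
    0.086866,
    0.290216,
    0.501008,
    0.343406
   ]
  }
 ],
 "N": [
  {
   "l": 0,
   "exp": [
    11420,
    1712,
    389.3,
    110,
    35.57,
    12.54,
    4.644,
    1.293,
    0.5118,
    0.1787
   ],
   "coef": [
    0.000523,
    0.004045,
    0.020775,
    0.080727,
    0.233074,
    0.433501,
    0.347472,
    0.041262,
    -0.008508,
    0.002384
   ]
  },
  {
   "l": 0,
   "exp": [
    11420,
    1712,
    389.3,
    110,
    35.57,
    12.54,
    4.644,
    1.293,
    0.5118,
    0.1787
   ],
   "coef": [
    -0.000115,
    -0.000895,
    -0.004624,
    -0.018528,
    -0.057339,
    -0.132076,
    -0.17251,
    0.151814,
    0.599944,
    0.387462
   ]
  },
  {
   "l": 1,
   "exp": [
    26.63,
    5.948,
    1.742,
    0.555,
    0.1725
   ],
   "coef": [
    0.01467,
    0.091764,
    0.298683,
    0.498487,
    0.337023
   ]
  }
 ],
 "O": [
  {
   "l": 0,
   "exp": [
    15330,
    2299,
    522.4,
    147.3,
    47.55,
    16.76,
    6.207,
    1.752,
    0.6882,
    0.2384
   ],
   "coef": [
    0.000508,
    0.003929,
    0.020243,
    0.079181,
    0.230687,
    0.433118,
    0.35026,
    0.042728,
    -0.008154,
    0.002381
   ]
  },
  {
   "l": 0,
   "exp": [
    15330,
    2299,
    522.4,
    147.3,
    47.55,
    16.76,
    6.207,
    1.752,
    0.6882,
    0.2384
   ],
   "coef": [
    -0.000115,
    -0.000895,
    -0.004636,
    -0.018724,
    -0.058463,
    -0.136463,
    -0.17574,
    0.160934,
    0.603418,
    0.378765
   ]
  },
  {
   "l": 1,
   "exp": [
    34.46,
    7.749,
    2.28,
    0.7156,
    0.214
   ],
   "coef": [
    0.015928,
    0.09974,
    0.310492,
    0.491026,
    0.336337
   ]
  }
 ],
 "F": [
  {
   "l": 0,
   "exp": [
    19500,
    2923,
    664.5,
    187.5,
    60.62,
    21.42,
    7.95,
    2.257,
    0.8815,
    0.3041
   ],
   "coef": [
    0.000507,
    0.003923,
    0.0202,
    0.07901,
    0.230439,
    0.432872,
    0.349964,
    0.043233,
    -0.007892,
    0.002384
   ]
  },
  {
   "l": 0,
   "exp": [
    19500,
    2923,
    664.5,
    187.5,
    60.62,
    21.42,
    7.95,
    2.257,
    0.8815,
    0.3041
   ],
   "coef": [
    -0.000117,
    -0.000912,
    -0.004717,
    -0.019086,
    -0.059655,
    -0.14001,
    -0.176782,
    0.171625,
    0.605043,
    0.369512
   ]
  },
  {
   "l": 1,
   "exp": [
    43.88,
    9.926,
    2.93,
    0.9132,
    0.2672
   ],
   "coef": [
    0.016665,
    0.104472,
    0.31726,
    0.487343,
    0.334604
   ]
  }
 ]
}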