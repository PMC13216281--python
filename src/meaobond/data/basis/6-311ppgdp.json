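{
 "H": [
  {
   "l": 0,
   "exp": [
    33.865,
    5.09479,
    1.15879
   ],
   "coef": [
    0.0254938,
    0.190373,
    0.852161
   ]
  },
  {
   "l": 0,
   "exp": [
    0.32584
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.102741
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.036
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.75
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
    98.1243,
    14.7689,
    3.31883
   ],
   "coef": [
    0.0287452,
    0.208061,
    0.837635
   ]
  },
  {
   "l": 0,
   "exp": [
    0.874047
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.244564
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.75
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
    900.46,
    134.433,
    30.4365,
    8.62639,
    2.48332,
    0.303179
   ],
   "coef": [
    0.00228704,
    0.017635,
    0.0873434,
    0.280977,
    0.658741,
    0.118712
   ]
  },
  {
   "l": 0,
   "exp": [
    4.8689,
    0.856924,
    0.243227
   ],
   "coef": [
    0.0933293,
    0.943045,
    -0.00279827
   ]
  },
  {
   "l": 0,
   "exp": [
    0.063507
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.0243683
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.0074
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    4.8689,
    0.856924,
    0.243227
   ],
   "coef": [
    0.0327661,
    0.159792,
    0.885667
   ]
  },
  {
   "l": 1,
   "exp": [
    0.063507
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.0243683
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.0074
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    0.2
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
    2858.89,
    428.14,
    97.5282,
    27.9693,
    8.21577,
    1.11278
   ],
   "coef": [
    0.00215375,
    0.0165823,
    0.082187,
    0.276618,
    0.629316,
    0.17377
   ]
  },
  {
   "l": 0,
   "exp": [
    13.2415,
    3.00166,
    0.912856
   ],
   "coef": [
    0.117443,
    0.918002,
    -0.00265105
   ]
  },
  {
   "l": 0,
   "exp": [
    0.315454
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.0988563
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.0315
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    13.2415,
    3.00166,
    0.912856
   ],
   "coef": [
    0.04181,
    0.236575,
    0.816214
   ]
  },
  {
   "l": 1,
   "exp": [
    0.315454
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.0988563
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.0315
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    0.401
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
    4563.24,
    682.024,
    154.973,
    44.4553,
    13.029,
    1.82773
   ],
   "coef": [
    0.00196665,
    0.0152306,
    0.0761269,
    0.260801,
    0.616462,
    0.221006
   ]
  },
  {
   "l": 0,
   "exp": [
    20.9642,
    4.80331,
    1.45933
   ],
   "coef": [
    0.11466,
    0.919999,
    -0.00303068
   ]
  },
  {
   "l": 0,
   "exp": [
    0.483456
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.145585
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.0438
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    20.9642,
    4.80331,
    1.45933
   ],
   "coef": [
    0.0402487,
    0.237594,
    0.815854
   ]
  },
  {
   "l": 1,
   "exp": [
    0.483456
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.145585
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.0438
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    0.626
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
    6293.48,
    949.044,
    218.776,
    63.6916,
    18.8282,
    2.72023
   ],
   "coef": [
    0.00196979,
    0.0149613,
    0.0735006,
    0.248937,
    0.60246,
    0.256202
   ]
  },
  {
   "l": 0,
   "exp": [
    30.6331,
    7.02614,
    2.11205
   ],
   "coef": [
    0.111906,
    0.921666,
    -0.00256919
   ]
  },
  {
   "l": 0,
   "exp": [
    0.684009
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.200878
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.0639
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    30.6331,
    7.02614,
    2.11205
   ],
   "coef": [
    0.0383119,
    0.237403,
    0.817592
   ]
  },
  {
   "l": 1,
   "exp": [
    0.684009
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.200878
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.0639
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    0.913
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
    8588.5,
    1297.23,
    299.296,
    87.3771,
    25.6789,
    3.74004
   ],
   "coef": [
    0.00189515,
    0.0143859,
    0.070732,
    0.240001,
    0.594797,
    0.280802
   ]
  },
  {
   "l": 0,
   "exp": [
    42.1175,
    9.62837,
    2.85332
   ],
   "coef": [
    0.113889,
    0.920811,
    -0.00327447
   ]
  },
  {
   "l": 0,
   "exp": [
    0.905661
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.255611
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.0845
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    42.1175,
    9.62837,
    2.85332
   ],
   "coef": [
    0.0365114,
    0.237153,
    0.819702
   ]
  },
  {
   "l": 1,
   "exp": [
    0.905661
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.255611
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.0845
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    1.292
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
    11427.1,
    1722.35,
    395.746,
    115.139,
    33.6026,
    4.91901
   ],
   "coef": [
    0.00180093,
    0.0137419,
    0.0681334,
    0.233325,
    0.589086,
    0.299505
   ]
  },
  {
   "l": 0,
   "exp": [
    55.4441,
    12.6323,
    3.71756
   ],
   "coef": [
    0.114536,
    0.920512,
    -0.00337804
   ]
  },
  {
   "l": 0,
   "exp": [
    1.16545
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.321892
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 0,
   "exp": [
    0.1076
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    55.4441,
    12.6323,
    3.71756
   ],
   "coef": [
    0.0354609,
    0.237451,
    0.820458
   ]
  },
  {
   "l": 1,
   "exp": [
    1.16545
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.321892
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 1,
   "exp": [
    0.1076
   ],
   "coef": [
    1.0
   ]
  },
  {
   "l": 2,
   "exp": [
    1.75
   ],
   "coef": [
    1.0
   ]
  }
 ]
}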