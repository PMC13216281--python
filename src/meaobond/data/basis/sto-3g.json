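{
 "H": [
  {
   "l": 0,
   "exp": [
    3.42525091,
    0.62391373,
    0.1688554
   ],
   "coef": [
    0.15432897,
    0.53532814,
    0.44463454
   ]
  }
 ],
 "He": [
  {
   "l": 0,
   "exp": [
    6.36242139,
    1.158923,
    0.31364979
   ],
   "coef": [
    0.15432897,
    0.53532814,
    0.44463454
   ]
  }
 ],
 "Li": [
  {
   "l": 0,
   "exp": [
    16.119575,
    2.9362007,
    0.7946505
   ],
   "coef": [
    0.15432897,
    0.53532814,
    0.44463454
   ]
  },
  {
   "l": 0,
   "exp": [
    0.6362897,
    0.1478601,
    0.0480887
   ],
   "coef": [
    -0.09996723,
    0.39951283,
    0.70011547
   ]
  },
  {
   "l": 1,
   "exp": [
    0.6362897,
    0.1478601,
    0.0480887
   ],
   "coef": [
    0.15591627,
    0.60768372,
    0.39195739
   ]
  }
 ],
 "B": [
  {
   "l": 0,
   "exp": [
    48.791113,
    8.8873622,
    2.405267
   ],
   "coef": [
    0.15432897,
    0.53532814,
    0.44463454
   ]
  },
  {
   "l": 0,
   "exp": [
    2.2369561,
    0.5198205,
    0.1690618
   ],
   "coef": [
    -0.09996723,
    0.39951283,
    0.70011547
   ]
  },
  {
   "l": 1,
   "exp": [
    2.2369561,
    0.5198205,
    0.1690618
   ],
   "coef": [
    0.15591627,
    0.60768372,
    0.39195739
   ]
  }
 ],
 "C": [
  {
   "l": 0,
   "exp": [
    71.616837,
    13.045096,
    3.5305122
   ],
   "coef": [
    0.15432897,
    0.53532814,
    0.44463454
   ]
  },
  {
   "l": 0,
   "exp": [
    2.9412494,
    0.6834831,
    0.2222899
   ],
   "coef": [
    -0.09996723,
    0.39951283,
    0.70011547
   ]
  },
  {
   "l": 1,
   "exp": [
    2.9412494,
    0.6834831,
    0.2222899
   ],
   "coef": [
    0.15591627,
    0.60768372,
    0.39195739
   ]
  }
 ],
 "N": [
  {
   "l": 0,
   "exp": [
    99.106169,
    18.052312,
    4.8856602
   ],
   "coef": [
    0.15432897,
    0.53532814,
    0.44463454
   ]
  },
  {
   "l": 0,
   "exp": [
    3.7804559,
    0.8784966,
    0.2857144
   ],
   "coef": [
    -0.09996723,
    0.39951283,
    0.70011547
   ]
  },
  {
   "l": 1,
   "exp": [
    3.7804559,
    0.8784966,
    0.2857144
   ],
   "coef": [
    0.15591627,
    0.60768372,
    0.39195739
   ]
  }
 ],
 "O": [
  {
   "l": 0,
   "exp": [
    130.70932,
    23.808861,
    6.4436083
   ],
   "coef": [
    0.15432897,
    0.53532814,
    0.44463454
   ]
  },
  {
   "l": 0,
   "exp": [
    5.0331513,
    1.1695961,
    0.380389
   ],
   "coef": [
    -0.09996723,
    0.39951283,
    0.70011547
   ]
  },
  {
   "l": 1,
   "exp": [
    5.0331513,
    1.1695961,
    0.380389
   ],
   "coef": [
    0.15591627,
    0.60768372,
    0.39195739
   ]
  }
 ],
 "F": [
  {
   "l": 0,
   "exp": [
    166.67913,
    30.360812,
    8.2168207
   ],
   "coef": [
    0.15432897,
    0.53532814,
    0.44463454
   ]
  },
  {
   "l": 0,
   "exp": [
    6.4648032,
    1.5022812,
    0.4885885
   ],
   "coef": [
    -0.09996723,
    0.39951283,
    0.70011547
   ]
  },
  {
   "l": 1,
   "exp": [
    6.4648032,
    1.5022812,
    0.4885885
   ],
   "coef": [
    0.15591627,
    0.60768372,
    0.39195739
   ]
  }
 ]
}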