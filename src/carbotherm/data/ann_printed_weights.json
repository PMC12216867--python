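{
 "architecture": [
  6,
  32,
  3
 ],
 "inputs": [
  "t_c",
  "v_c",
  "t_m",
  "dh_m",
  "molality",
  "temperature"
 ],
 "outputs": [
  "phi",
  "gamma",
  "a_w"
 ],
 "w_ih": [
  [
   -1.6033,
   0.8398,
   0.0669,
   1.8173,
   0.9064,
   2.2894,
   -0.2195,
   -0.5824,
   1.2127,
   -2.1116,
   -1.2338,
   -1.8254,
   -0.5673,
   1.2737,
   1.3342,
   -1.9886,
   -0.5034,
   0.0985,
   -0.3746,
   0.6239,
   0.7887,
   -1.2946,
   -0.2769,
   -2.0382,
   1.9632,
   -1.952,
   -1.2269,
   -0.8317,
   -1.0883,
   -0.0657,
   -1.2475,
   1.8882
  ],
  [
   1.9248,
   -2.3537,
   0.8562,
   -0.8871,
   -0.4694,
   0.3649,
   2.1029,
   -0.7085,
   1.8007,
   -1.0065,
   0.6764,
   0.9297,
   0.2035,
   0.7615,
   0.7324,
   -1.4563,
   -1.8589,
   1.8289,
   -1.4808,
   -1.8592,
   0.3772,
   2.3766,
   0.6855,
   -1.3022,
   -0.5316,
   -0.2303,
   1.5006,
   -2.2399,
   1.2817,
   0.9226,
   -0.9616,
   -1.2922
  ],
  [
   -0.3285,
   -0.0946,
   -1.3657,
   0.3439,
   -1.6658,
   -0.8795,
   0.3942,
   -2.1379,
   -0.7812,
   0.5936,
   -0.7894,
   1.8129,
   2.5105,
   0.885,
   -0.6867,
   0.3804,
   -1.9601,
   1.4889,
   1.7094,
   1.264,
   -1.4746,
   0.5872,
   -1.9347,
   -0.3144,
   -0.7595,
   -1.9853,
   -1.0009,
   -0.5027,
   -1.4629,
   0.6279,
   -0.226,
   0.8192
  ],
  [
   0.9153,
   0.7289,
   -1.6789,
   -1.6567,
   -1.0975,
   0.2353,
   0.7336,
   -0.7958,
   1.1928,
   1.107,
   1.5762,
   0.1751,
   -0.9095,
   -1.5159,
   0.488,
   1.2614,
   -0.3825,
   -1.4994,
   -1.0514,
   -1.3777,
   -1.3497,
   -0.3729,
   0.11,
   -0.1791,
   1.5224,
   0.1059,
   1.3822,
   0.8977,
   1.6501,
   -1.6525,
   1.3689,
   -0.8819
  ],
  [
   0.7867,
   1.0268,
   -1.5551,
   -0.9421,
   -1.6789,
   1.2794,
   1.6358,
   -1.3398,
   1.0457,
   0.8889,
   -1.6591,
   0.571,
   -0.5889,
   1.599,
   -2.194,
   -0.1699,
   -0.378,
   -0.1432,
   1.2164,
   -0.7062,
   1.7549,
   -0.1783,
   -1.881,
   -1.3635,
   0.8994,
   -0.1555,
   -1.082,
   -1.0357,
   0.3872,
   -1.9645,
   1.8531,
   -1.0751
  ],
  [
   1.5442,
   0.0859,
   -1.4916,
   -0.7423,
   -1.0616,
   2.3505,
   -0.6156,
   0.7481,
   -0.1924,
   0.8886,
   -0.7648,
   -1.4023,
   -1.4224,
   0.4882,
   -0.1774,
   -0.1961,
   1.4193,
   0.2916,
   0.1978,
   1.5877,
   -0.8045,
   0.6966,
   0.8351,
   -0.2437,
   0.2157,
   -1.1658,
   -1.148,
   0.1049,
   0.7223,
   2.5855,
   -0.6669,
   0.1873
  ]
 ],
 "b_h": [
  2.8,
  -2.6194,
  -2.4387,
  -2.2581,
  -2.0774,
  -1.8968,
  1.7161,
  1.5355,
  -1.3548,
  1.1742,
  0.9935,
  0.8129,
  0.6323,
  -0.4516,
  -0.271,
  0.0903,
  -0.0903,
  0.271,
  -0.4516,
  0.6323,
  0.8129,
  -0.9935,
  -1.1742,
  -1.3548,
  1.5355,
  -1.7161,
  -1.8968,
  -2.0774,
  -2.2581,
  -2.4387,
  -2.6194,
  2.8
 ],
 "w_ho": [
  [
   0.8348,
   -0.4619,
   0.531
  ],
  [
   -0.6227,
   -0.425,
   -0.8178
  ],
  [
   0.1524,
   0.3667,
   0.0932
  ],
  [
   -0.1485,
   0.2889,
   0.2952
  ],
  [
   0.358,
   0.2716,
   0.8903
  ],
  [
   -0.5821,
   0.4186,
   -0.5275
  ],
  [
   -0.7612,
   0.2146,
   -0.0997
  ],
  [
   -0.0825,
   0.3239,
   0.5406
  ],
  [
   -0.2996,
   0.324,
   -0.1677
  ],
  [
   0.6839,
   0.6658,
   -0.4871
  ],
  [
   0.2269,
   0.1645,
   0.0815
  ],
  [
   0.7399,
   -0.4704,
   -0.3639
  ],
  [
   -0.7616,
   0.8797,
   0.2911
  ],
  [
   -0.0411,
   0.2786,
   0.0894
  ],
  [
   0.2946,
   0.0878,
   0.4421
  ],
  [
   0.045,
   0.9874,
   -0.5626
  ],
  [
   -0.7884,
   -0.7806,
   -0.8728
  ],
  [
   -0.1908,
   -0.1033,
   -0.2684
  ],
  [
   0.527,
   0.2558,
   0.544
  ],
  [
   0.8657,
   0.9455,
   -0.6159
  ],
  [
   -0.7223,
   0.3925,
   -0.8124
  ],
  [
   0.0508,
   0.0607,
   0.7223
  ],
  [
   -0.0303,
   -0.2131,
   0.3429
  ],
  [
   0.4825,
   0.0401,
   -0.3046
  ],
  [
   -0.7,
   0.1722,
   -0.4757
  ],
  [
   -0.9111,
   0.5099,
   -0.5144
  ],
  [
   -0.1152,
   0.3756,
   -0.2815
  ],
  [
   0.4727,
   -0.2106,
   0.3668
  ],
  [
   0.4081,
   -0.1154,
   -0.9608
  ],
  [
   -0.3383,
   -0.1514,
   -0.4595
  ],
  [
   -0.6059,
   0.6434,
   -0.1402
  ],
  [
   0.7755,
   -0.2176,
   0.5382
  ]
 ],
 "b_o": [
  -0.2064,
  0.617,
  0.5102
 ],
 "input_scaling": null,
 "output_scaling": null,
 "note": "printed weights; input/output scaling was not published, so forward passes are supported only for sensitivity analysis unless the user supplies scaling"
}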