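{
 "clusters": [
  {
   "id": "0",
   "size": 352,
   "t_ferro": 0.00227273,
   "t_cl": 0.0431818,
   "s_t": null,
   "members": null
  },
  {
   "id": "1",
   "size": 300,
   "t_ferro": 0.00227273,
   "t_cl": 0.0318182,
   "s_t": null,
   "members": null
  },
  {
   "id": "1 1",
   "size": 267,
   "t_ferro": 0.00681818,
   "t_cl": 0.00909091,
   "s_t": null,
   "members": null
  },
  {
   "id": "1 1 1",
   "size": 135,
   "t_ferro": 0.0181818,
   "t_cl": null,
   "s_t": 0.666667,
   "members": [
    14,
    16,
    26,
    34,
    41,
    42,
    44,
    45,
    46,
    54,
    55,
    57,
    63,
    81,
    161,
    162,
    163,
    164,
    165,
    166,
    167,
    168,
    169,
    170,
    171,
    172,
    173,
    175,
    176,
    177,
    178,
    179,
    180,
    181,
    182,
    183,
    184,
    185,
    187,
    188,
    189,
    190,
    191,
    192,
    193,
    194,
    195,
    196,
    198,
    202,
    205,
    206,
    207,
    208,
    209,
    210,
    211,
    212,
    213,
    214,
    215,
    216,
    217,
    218,
    222,
    235,
    236,
    237,
    238,
    239,
    240,
    241,
    242,
    243,
    244,
    245,
    246,
    247,
    248,
    250,
    251,
    252,
    253,
    254,
    255,
    256,
    257,
    258,
    259,
    260,
    261,
    262,
    263,
    265,
    266,
    267,
    269,
    271,
    272,
    273,
    274,
    275,
    276,
    277,
    278,
    279,
    280,
    281,
    282,
    283,
    285,
    286,
    287,
    289,
    290,
    291,
    292,
    293,
    294,
    295,
    296,
    297,
    298,
    299,
    300,
    301,
    302,
    303,
    304,
    305,
    306,
    307,
    309,
    310,
    326
   ]
  },
  {
   "id": "1 1 2",
   "size": 132,
   "t_ferro": 0.0181818,
   "t_cl": null,
   "s_t": null,
   "members": [
    4,
    5,
    6,
    7,
    12,
    13,
    15,
    17,
    19,
    22,
    32,
    33,
    35,
    37,
    40,
    43,
    47,
    49,
    50,
    51,
    52,
    53,
    56,
    58,
    59,
    60,
    62,
    64,
    68,
    71,
    72,
    73,
    74,
    75,
    76,
    77,
    78,
    79,
    80,
    82,
    83,
    84,
    85,
    86,
    87,
    88,
    89,
    90,
    94,
    98,
    101,
    102,
    103,
    104,
    105,
    106,
    107,
    108,
    109,
    110,
    111,
    132,
    134,
    135,
    136,
    137,
    140,
    141,
    142,
    144,
    151,
    152,
    153,
    154,
    155,
    156,
    174,
    186,
    197,
    199,
    200,
    201,
    203,
    204,
    249,
    264,
    268,
    270,
    284,
    288,
    308,
    311,
    312,
    313,
    314,
    315,
    316,
    317,
    318,
    319,
    320,
    321,
    322,
    323,
    324,
    325,
    327,
    328,
    329,
    330,
    331,
    332,
    333,
    334,
    335,
    336,
    337,
    338,
    339,
    340,
    341,
    342,
    343,
    344,
    345,
    346,
    347,
    348,
    349,
    350,
    351,
    352
   ]
  },
  {
   "id": "1 2",
   "size": 33,
   "t_ferro": 0.00227273,
   "t_cl": null,
   "s_t": null,
   "members": [
    10,
    11,
    18,
    29,
    30,
    31,
    38,
    39,
    67,
    69,
    95,
    112,
    113,
    114,
    115,
    116,
    117,
    118,
    119,
    120,
    121,
    122,
    123,
    131,
    133,
    139,
    145,
    147,
    148,
    149,
    150,
    158,
    160
   ]
  },
  {
   "id": "2",
   "size": 52,
   "t_ferro": 0.0,
   "t_cl": null,
   "s_t": null,
   "members": [
    1,
    2,
    3,
    8,
    9,
    20,
    21,
    23,
    24,
    25,
    27,
    28,
    36,
    48,
    61,
    65,
    66,
    70,
    91,
    92,
    93,
    96,
    97,
    99,
    100,
    124,
    125,
    126,
    127,
    128,
    129,
    130,
    138,
    143,
    146,
    157,
    159,
    219,
    220,
    221,
    223,
    224,
    225,
    226,
    227,
    228,
    229,
    230,
    231,
    232,
    233,
    234
   ]
  }
 ]
}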