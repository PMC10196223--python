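subregion,pop,altitude_m,lat,lon,n,ci,theta
Lesser Caucasus,LC1,187,41.6842,41.8345,30,1.33,1.19
Lesser Caucasus,LC2,971,41.7287,42.0781,30,3.11,0.97
Lesser Caucasus,LC3,465,41.9293,42.3735,33,4.61,0.72
Lesser Caucasus,LC4,582,41.9581,42.7696,31,3.62,0.85
Likhi range,LR1,365,42.1429,43.1068,30,4.11,1.18
Likhi range,LR2,899,42.0437,43.4988,30,5.02,0.63
Western Greater Caucasus,WGC1,595,42.3442,43.5264,30,3.83,0.58
Western Greater Caucasus,WGC2,756,42.5205,43.1896,29,4.32,1.28
Western Greater Caucasus,WGC3,775,42.5038,43.1462,33,3.77,0.80
Western Greater Caucasus,WGC4,574,42.3557,42.9991,31,2.82,0.86
Western Greater Caucasus,WGC5,537,42.3329,42.9421,28,3.76,0.16
Western Greater Caucasus,WGC6,913,42.6569,42.4341,29,2.40,1.12
Western Greater Caucasus,WGC7,343,42.6548,42.2216,31,1.99,0.84
Central Greater Caucasus,CGC1,806,42.2226,45.3037,18,4.66,0.70
Central Greater Caucasus,CGC2,679,41.9472,45.9865,30,2.21,0.38
Central Greater Caucasus,CGC3,559,41.9326,46.0194,27,2.48,0.70
Central Greater Caucasus,CGC4,691,41.8854,46.2457,22,1.76,0.76
Eastern Greater Caucasus,EGC1,963,41.6796,46.6864,33,0.97,0.89
Eastern Greater Caucasus,EGC2,670,41.6194,46.6990,31,1.65,0.77
Eastern Greater Caucasus,EGC3,852,41.2976,47.1249,29,1.18,0.86
Eastern Greater Caucasus,EGC4,1058,40.9883,47.9544,41,2.01,0.44
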