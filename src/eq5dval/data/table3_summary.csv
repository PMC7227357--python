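state,method,n,mean,sd,p25,p50,p75
11111,VAS,313,1.0000,0.0000,1,1,1
31122,VAS,313,0.6874,0.1628,0.6,0.7,0.8
22113,VAS,313,0.5679,0.1858,0.4,0.6,0.7
13212,VAS,313,0.6178,0.1797,0.5,0.6,0.7
12321,VAS,313,0.5882,0.1577,0.5,0.6,0.7
21231,VAS,313,0.5171,0.1377,0.4,0.5,0.6
22222,VAS,313,0.4613,0.1468,0.4,0.5,0.5
23311,VAS,313,0.4451,0.1387,0.4,0.4,0.5
11332,VAS,313,0.4300,0.1454,0.3,0.4,0.5
32131,VAS,313,0.3962,0.1422,0.3,0.4,0.5
31213,VAS,313,0.4962,0.1857,0.4,0.5,0.6
13123,VAS,313,0.4553,0.1307,0.4,0.5,0.6
12233,VAS,313,0.4335,0.1921,0.3,0.4,0.6
33221,VAS,313,0.4764,0.2063,0.3,0.4,0.6
21323,VAS,313,0.4006,0.1817,0.3,0.4,0.6
23132,VAS,313,0.3946,0.2201,0.2,0.4,0.5
32312,VAS,313,0.3884,0.2301,0.2,0.4,0.5
33333,VAS,313,-0.1378,0.2465,-0.2,-0.1,0
total,VAS,5634,0.4788,0.2703,0.3,0.5,0.6
11111,TTO,313,1.0000,0.0000,1,1,1
31122,TTO,313,0.6125,0.1685,0.5,0.6,0.7
22113,TTO,313,0.5193,0.1613,0.4,0.5,0.6
13212,TTO,313,0.4867,0.1632,0.4,0.5,0.6
12321,TTO,313,0.5025,0.1465,0.4,0.5,0.6
21231,TTO,313,0.4816,0.1383,0.4,0.5,0.5
22222,TTO,313,0.4155,0.1556,0.3,0.4,0.5
23311,TTO,313,0.4300,0.1483,0.4,0.4,0.5
11332,TTO,313,0.4503,0.1446,0.4,0.5,0.5
32131,TTO,313,0.3963,0.1486,0.3,0.4,0.5
31213,TTO,313,0.3980,0.1450,0.3,0.4,0.5
13123,TTO,313,0.4426,0.1431,0.4,0.5,0.5
12233,TTO,313,0.3842,0.1941,0.3,0.4,0.5
33221,TTO,313,0.3835,0.1412,0.3,0.4,0.4
21323,TTO,313,0.3647,0.1381,0.3,0.4,0.4
23132,TTO,313,0.2794,0.1550,0.2,0.2,0.3
32312,TTO,313,0.2904,0.1428,0.2,0.3,0.3
33333,TTO,313,-0.0801,0.1509,-0.125,-0.1,-0.028
total,TTO,5634,0.4310,0.2457,0.3,0.4,0.5
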