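age,sex,qx
0,m,0.00024996875260396845
1,m,0.0002546675667086662
2,m,0.00025980804404324154
3,m,0.00026543169597259553
4,m,0.00027158393494941535
5,m,0.00027831444102455194
6,m,0.00028567756276942635
7,m,0.00029373275584165803
8,m,0.0003025450627196502
9,m,0.0003121856374685983
10,m,0.0003227323197558807
11,m,0.00033427026273069593
12,m,0.0003468926198132438
13,m,0.00036070129590815014
14,m,0.00037580776907242264
15,m,0.000392333989229221
16,m,0.00041041336113145643
17,m,0.0004301918194502541
18,m,0.00045182900459406206
19,m,0.00047549954866332733
20,m,0.0005013944818137439
21,m,0.0005297227702584228
22,m,0.0005607129981678449
23,m,0.0005946152068658783
24,m,0.0006317029059471624
25,m,0.0006722752722868597
26,m,0.0007166595543812715
27,m,0.0007652137010448756
28,m,0.0008183292352335059
29,m,0.0008764343956445542
30,m,0.0009399975708028752
31,m,0.0010095310525694012
32,m,0.0010855951384363127
33,m,0.0011688026145967312
34,m,0.0012598236546352837
35,m,0.001359391171766977
36,m,0.0014683066659013644
37,m,0.001587446610416654
38,m,0.001717769427432847
39,m,0.001860323104575845
40,m,0.002016253510751853
41,m,0.0021868134733111777
42,m,0.0023733726841981273
43,m,0.002577428508256374
44,m,0.0028006177728107096
45,m,0.003044729623973619
46,m,0.0033117195418335132
47,m,0.003603724613762349
48,m,0.003923080172520854
49,m,0.004272337913614588
50,m,0.004654285614425602
51,m,0.005071968585954378
52,m,0.0055287129964857185
53,m,0.006028151215028199
54,m,0.006574249330850157
55,m,0.007171337013664458
56,m,0.007824139886786874
57,m,0.00853781459264047
58,m,0.009317986735952632
59,m,0.010170791894485998
60,m,0.011102919889629193
61,m,0.012121662509038567
62,m,0.013234964869988985
63,m,0.014451480604249278
64,m,0.01578063103203642
65,m,0.017232668472599744
66,m,0.01881874381065818
67,m,0.020550978399399566
68,m,0.022442540329835503
69,m,0.02450772503040055
70,m,0.02676204007676286
71,m,0.029222293986356007
72,m,0.03190668864109092
73,m,0.034834914820407126
74,m,0.03802825012998168
75,m,0.04150965837306397
76,m,0.04530388912489214
77,m,0.04943757592864828
78,m,0.05393933112598892
79,m,0.05883983485791866
80,m,0.06417191521394416
81,m,0.06997061586037845
82,m,0.076273246734192
83,m,0.08311941253991162
84,m,0.0905510128288487
85,m,0.0986122063707704
86,m,0.10734933135133684
87,m,0.1168107716545348
88,m,0.1270467581378909
89,m,0.13810909241229596
90,m,0.15005077924750498
91,m,0.16292555241000073
92,m,0.17678727760007495
93,m,0.19168921532067973
94,m,0.20768312615207718
95,m,0.22481820123910023
96,m,0.24313980208815256
97,m,0.26268799633896445
98,m,0.28349588039513274
99,m,0.30558768608837006
100,m,1.0
0,f,0.00022797400997531803
1,f,0.00023060540648478511
2,f,0.00023348414633317383
3,f,0.00023663347823288383
4,f,0.00024007883596799395
5,f,0.0002438480437302326
6,f,0.0002479715407454064
7,f,0.00025248262699939517
8,f,0.000257417732046461
9,f,0.0002628167090638067
10,f,0.0002687231565244863
11,f,0.0002751847700768195
12,f,0.000282253727466264
13,f,0.00028998710959782237
14,f,0.00029844736112838444
15,f,0.0003077027942949284
16,f,0.00031782814002978554
17,f,0.00032890515079631033
18,f,0.0003410232599873053
19,f,0.00035428030318407355
20,f,0.000368783307066356
21,f,0.00038464935230442254
22,f,0.00040200651735089465
23,f,0.0004209949106978028
24,f,0.00044176779986249137
25,f,0.0004644928461382536
26,f,0.0004893534549772482
27,f,0.0005165502527932908
28,f,0.0005463027019634303
29,f,0.0005788508668990167
30,f,0.000614457345240127
31,f,0.0006534093795205198
32,f,0.0006960211660588245
33,f,0.0007426363793654467
34,f,0.0007936309320247803
35,f,0.0008494159918293054
36,f,0.0009104412799207928
37,f,0.0009771986758397855
38,f,0.0010502261577216565
39,f,0.0011301121084101862
40,f,0.0012175000210081777
41,f,0.001313093640364582
42,f,0.0014176625802228005
43,f,0.0015320484592409311
44,f,0.001657171602867047
45,f,0.001794038362112671
46,f,0.0019437491046495614
47,f,0.0021075069383608147
48,f,0.002286627232529592
49,f,0.0024825480072611095
50,f,0.0026968412675099085
51,f,0.002931225364242507
52,f,0.003187578471801955
53,f,0.0034679532774503086
54,f,0.003774592986348857
55,f,0.004109948752861303
56,f,0.004476698657007283
57,f,0.0048777683531038285
58,f,0.0053163535260464245
59,f,0.005795944299203826
60,f,0.006320351746423869
61,f,0.006893736669009276
62,f,0.00752064080653303
63,f,0.008206020657778201
64,f,0.008955284094594118
65,f,0.009774329956684036
66,f,0.010669590818809915
67,f,0.011648079123035449
68,f,0.012717436866746534
69,f,0.01388598903142102
70,f,0.015162800926475262
71,f,0.01655773960574425
72,f,0.018081539489820164
73,f,0.0197458722938324
74,f,0.02156342131526423
75,f,0.023547960077646146
76,f,0.02571443525062611
77,f,0.028079053671702714
78,f,0.030659373176014526
79,f,0.03347439679362052
80,f,0.03654466969369785
81,f,0.039892378036352705
82,f,0.043541448628957036
83,f,0.04751764796805358
84,f,0.05184867887225664
85,f,0.056564272467981236
86,f,0.061696272769655724
87,f,0.06727871049055711
88,f,0.07334786202110555
89,f,0.07994228871070264
90,f,0.08710285068103463
91,f,0.09487268837986806
92,f,0.1032971639556195
93,f,0.11242375330122145
94,f,0.12230187829625405
95,f,0.13298266739551257
96,f,0.14451863131164466
97,f,0.15696323918003385
98,f,0.17037037936093458
99,f,0.18479368804230578
100,f,1.0
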