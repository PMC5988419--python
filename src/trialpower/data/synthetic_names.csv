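name,p_female,count
Anna,0.9,500
Maria,0.9011,537
Emma,0.9022,574
Olivia,0.9033,611
Sophia,0.9044,648
Isabella,0.9055,685
Mia,0.9066,722
Charlotte,0.9077,759
Amelia,0.9088,796
Harper,0.9099,833
Evelyn,0.911,870
Abigail,0.9121,907
Emily,0.9132,944
Elizabeth,0.9143,981
Sofia,0.9154,1018
Avery,0.9165,1055
Ella,0.9176,1092
Scarlett,0.9187,1129
Grace,0.9198,1166
Chloe,0.9209,1203
Victoria,0.922,1240
Riley,0.9231,1277
Aria,0.9242,1314
Lily,0.9253,1351
Hannah,0.9264,1388
Zoe,0.9275,1425
Nora,0.9286,1462
Stella,0.9297,1499
Aurora,0.9308,1536
Natalie,0.9319,1573
Savannah,0.933,1610
Brooklyn,0.9341,1647
Leah,0.9352,1684
Lucia,0.9363,1721
Paisley,0.9374,1758
Audrey,0.9385,1795
Skylar,0.9396,1832
Bella,0.9407,1869
Claire,0.9418,1906
Lucy,0.9429,1943
Anika,0.944,1980
Ingrid,0.9451,2017
Astrid,0.9462,2054
Freya,0.9473,2091
Sigrid,0.9484,2128
Elin,0.9495,2165
Maja,0.9506,2202
Linnea,0.9517,2239
Saga,0.9528,2276
Tuva,0.9539,2313
Giulia,0.955,2350
Chiara,0.9561,2387
Francesca,0.9572,2424
Alessia,0.9583,2461
Martina,0.9594,2498
Beatrice,0.9605,2535
Camilla,0.9616,2572
Elena,0.9627,2609
Irene,0.9638,2646
Paola,0.9649,2683
Marta,0.966,2720
Carmen,0.9671,2757
Pilar,0.9682,2794
Rosa,0.9693,2831
Dolores,0.9704,2868
Josefa,0.9715,2905
Antonia,0.9726,2942
Manuela,0.9737,2979
Blanca,0.9748,3016
Nuria,0.9759,3053
Yuki,0.977,3090
Sakura,0.9781,3127
Hana,0.9792,3164
Aiko,0.9803,3201
Emi,0.9814,3238
Mei,0.9825,3275
Rin,0.9836,3312
Yua,0.9847,3349
Himari,0.9858,3386
Akari,0.9869,3423
Priya,0.988,3460
Ananya,0.9891,3497
Diya,0.9902,3534
Ishita,0.9913,3571
Kavya,0.9924,3608
Meera,0.9935,3645
Pooja,0.9946,3682
Shreya,0.9957,3719
Tanvi,0.9968,3756
Aditi,0.9979,3793
James,0.1,600
John,0.0989,641
Robert,0.0978,682
Michael,0.0967,723
William,0.0956,764
David,0.0945,805
Richard,0.0934,846
Joseph,0.0923,887
Thomas,0.0912,928
Charles,0.0901,969
Christopher,0.089,1010
Daniel,0.0879,1051
Matthew,0.0868,1092
Anthony,0.0857,1133
Mark,0.0846,1174
Donald,0.0835,1215
Steven,0.0824,1256
Paul,0.0813,1297
Andrew,0.0802,1338
Joshua,0.0791,1379
Kenneth,0.078,1420
Kevin,0.0769,1461
Brian,0.0758,1502
George,0.0747,1543
Timothy,0.0736,1584
Ronald,0.0725,1625
Edward,0.0714,1666
Jason,0.0703,1707
Jeffrey,0.0692,1748
Ryan,0.0681,1789
Jacob,0.067,1830
Gary,0.0659,1871
Nicholas,0.0648,1912
Eric,0.0637,1953
Jonathan,0.0626,1994
Stephen,0.0615,2035
Larry,0.0604,2076
Justin,0.0593,2117
Scott,0.0582,2158
Brandon,0.0571,2199
Lars,0.056,2240
Erik,0.0549,2281
Sven,0.0538,2322
Bjorn,0.0527,2363
Gunnar,0.0516,2404
Olaf,0.0505,2445
Nils,0.0494,2486
Henrik,0.0483,2527
Magnus,0.0472,2568
Anders,0.0461,2609
Giovanni,0.045,2650
Marco,0.0439,2691
Luca,0.0428,2732
Alessandro,0.0417,2773
Andrea,0.0406,2814
Francesco,0.0395,2855
Matteo,0.0384,2896
Lorenzo,0.0373,2937
Davide,0.0362,2978
Stefano,0.0351,3019
Carlos,0.034,3060
Juan,0.0329,3101
Pedro,0.0318,3142
Miguel,0.0307,3183
Javier,0.0296,3224
Diego,0.0285,3265
Alejandro,0.0274,3306
Fernando,0.0263,3347
Pablo,0.0252,3388
Sergio,0.0241,3429
Hiroshi,0.023,3470
Takeshi,0.0219,3511
Kenji,0.0208,3552
Taro,0.0197,3593
Satoshi,0.0186,3634
Kazuo,0.0175,3675
Makoto,0.0164,3716
Osamu,0.0153,3757
Yuji,0.0142,3798
Akira,0.0131,3839
Arjun,0.012,3880
Rahul,0.0109,3921
Amit,0.0098,3962
Vijay,0.0087,4003
Sanjay,0.0076,4044
Rajesh,0.0065,4085
Suresh,0.0054,4126
Anil,0.0043,4167
Deepak,0.0032,4208
Manoj,0.0021,4249
Alex,0.5,200
Sam,0.5,211
Robin,0.5,222
Casey,0.5,233
Jordan,0.5,244
Taylor,0.5,255
Morgan,0.5,266
Jamie,0.5,277
Ariel,0.5,288
Kim,0.5,299
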