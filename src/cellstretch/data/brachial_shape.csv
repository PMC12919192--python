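t_frac,amplitude
0.000000,0.00000000
0.005000,0.00000001
0.010000,0.00000003
0.015000,0.00000007
0.020000,0.00000015
0.025000,0.00000029
0.030000,0.00000050
0.035000,0.00000085
0.040000,0.00000141
0.045000,0.00000229
0.050000,0.00000366
0.055000,0.00000577
0.060000,0.00000902
0.065000,0.00001395
0.070000,0.00002139
0.075000,0.00003251
0.080000,0.00004897
0.085000,0.00007315
0.090000,0.00010835
0.095000,0.00015915
0.100000,0.00023183
0.105000,0.00033491
0.110000,0.00047982
0.115000,0.00068177
0.120000,0.00096073
0.125000,0.00134269
0.130000,0.00186103
0.135000,0.00255825
0.140000,0.00348772
0.145000,0.00471575
0.150000,0.00632367
0.155000,0.00841005
0.160000,0.01109272
0.165000,0.01451070
0.170000,0.01882562
0.175000,0.02422262
0.180000,0.03091032
0.185000,0.03911982
0.190000,0.04910221
0.195000,0.06112460
0.200000,0.07546437
0.205000,0.09240145
0.210000,0.11220872
0.215000,0.13514047
0.220000,0.16141924
0.225000,0.19122132
0.230000,0.22466142
0.235000,0.26177729
0.240000,0.30251493
0.245000,0.34671543
0.250000,0.39410433
0.255000,0.44428446
0.260000,0.49673317
0.265000,0.55080471
0.270000,0.60573819
0.275000,0.66067155
0.280000,0.71466120
0.285000,0.76670722
0.290000,0.81578300
0.295000,0.86086843
0.300000,0.90098503
0.305000,0.93523150
0.310000,0.96281785
0.315000,0.98309630
0.320000,0.99558744
0.325000,1.00000000
0.330000,0.99624331
0.335000,0.98443164
0.340000,0.96488018
0.345000,0.93809298
0.350000,0.90474346
0.355000,0.86564855
0.360000,0.82173806
0.365000,0.77402072
0.370000,0.72354885
0.375000,0.67138323
0.380000,0.61855997
0.385000,0.56606074
0.390000,0.51478741
0.395000,0.46554210
0.400000,0.41901280
0.405000,0.37576484
0.410000,0.33623793
0.415000,0.30074808
0.420000,0.26949389
0.425000,0.24256621
0.430000,0.21996017
0.435000,0.20158879
0.440000,0.18729719
0.445000,0.17687663
0.450000,0.17007781
0.455000,0.16662279
0.460000,0.16621548
0.465000,0.16855030
0.470000,0.17331899
0.475000,0.18021588
0.480000,0.18894154
0.485000,0.19920512
0.490000,0.21072572
0.495000,0.22323299
0.500000,0.23646720
0.505000,0.25017910
0.510000,0.26412970
0.515000,0.27809012
0.520000,0.29184175
0.525000,0.30517657
0.530000,0.31789783
0.535000,0.32982109
0.540000,0.34077535
0.545000,0.35060458
0.550000,0.35916915
0.555000,0.36634749
0.560000,0.37203748
0.565000,0.37615788
0.570000,0.37864931
0.575000,0.37947511
0.580000,0.37862173
0.585000,0.37609868
0.590000,0.37193816
0.595000,0.36619411
0.600000,0.35894098
0.605000,0.35027196
0.610000,0.34029694
0.615000,0.32914017
0.620000,0.31693760
0.625000,0.30383417
0.630000,0.28998087
0.635000,0.27553194
0.640000,0.26064200
0.645000,0.24546336
0.650000,0.23014353
0.655000,0.21482295
0.660000,0.19963303
0.665000,0.18469448
0.670000,0.17011603
0.675000,0.15599345
0.680000,0.14240896
0.685000,0.12943092
0.690000,0.11711393
0.695000,0.10549913
0.700000,0.09461479
0.705000,0.08447709
0.710000,0.07509113
0.715000,0.06645202
0.720000,0.05854603
0.725000,0.05135191
0.730000,0.04484205
0.735000,0.03898380
0.740000,0.03374058
0.745000,0.02907307
0.750000,0.02494014
0.755000,0.02129985
0.760000,0.01811024
0.765000,0.01532998
0.770000,0.01291899
0.775000,0.01083890
0.780000,0.00905340
0.785000,0.00752849
0.790000,0.00623266
0.795000,0.00513699
0.800000,0.00421516
0.805000,0.00344341
0.810000,0.00280048
0.815000,0.00226749
0.820000,0.00182780
0.825000,0.00146683
0.830000,0.00117192
0.835000,0.00093215
0.840000,0.00073815
0.845000,0.00058193
0.850000,0.00045673
0.855000,0.00035687
0.860000,0.00027761
0.865000,0.00021499
0.870000,0.00016575
0.875000,0.00012722
0.880000,0.00009721
0.885000,0.00007395
0.890000,0.00005600
0.895000,0.00004221
0.900000,0.00003167
0.905000,0.00002366
0.910000,0.00001759
0.915000,0.00001301
0.920000,0.00000958
0.925000,0.00000702
0.930000,0.00000511
0.935000,0.00000370
0.940000,0.00000266
0.945000,0.00000190
0.950000,0.00000135
0.955000,0.00000094
0.960000,0.00000065
0.965000,0.00000044
0.970000,0.00000029
0.975000,0.00000019
0.980000,0.00000011
0.985000,0.00000006
0.990000,0.00000003
0.995000,0.00000001
1.000000,0.00000000
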