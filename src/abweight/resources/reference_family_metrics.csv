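Data_set,Family,MSE_GBLUP,COR_GBLUP,NRMSE_GBLUP,MSE_AB,COR_AB,NRMSE_AB
GDM,F1,119918.048,0.812,0.511,114336.072,0.824,0.488
GDM,F2,132406.015,0.840,0.515,126595.797,0.851,0.496
GDM,F3,128531.101,0.751,0.524,124833.302,0.768,0.501
GDM,F4,124508.028,0.837,0.473,118403.764,0.846,0.463
GDM,F5,110073.458,0.859,0.444,99472.574,0.877,0.432
GDM,F6,206341.443,0.801,0.543,175968.963,0.831,0.513
GDM,F7,124698.294,0.747,0.601,129174.949,0.737,0.600
GDM,F8,152335.628,0.760,0.600,141327.354,0.780,0.584
GDM,F9,137713.335,0.870,0.437,138444.200,0.872,0.434
GDM,F10,121695.210,0.822,0.483,112492.040,0.839,0.462
GDM,F11,119274.742,0.833,0.558,117417.465,0.834,0.560
GDM,F12,132365.930,0.863,0.470,132251.696,0.867,0.459
GDM,F13,108448.837,0.789,0.509,90377.859,0.826,0.470
Maize_1,Z001,6551.470,0.529,1.255,4220.248,0.593,1.051
Maize_1,Z002,1748.914,0.547,0.890,1715.049,0.627,0.857
Maize_1,Z003,2294.720,0.480,0.919,1834.473,0.622,0.817
Maize_1,Z004,2078.756,0.547,0.908,1865.140,0.636,0.889
Maize_1,Z005,2689.596,0.495,0.931,1978.842,0.637,0.801
Maize_1,Z006,2608.669,0.533,1.066,1638.615,0.659,0.876
Maize_2,Z006,2311.286,0.471,1.071,1338.993,0.661,0.937
Maize_2,Z007,2523.508,0.501,1.032,1421.342,0.667,0.804
Maize_2,Z008,4866.393,0.479,1.205,4367.755,0.636,1.110
Maize_2,Z009,3301.102,0.480,1.159,1578.735,0.631,0.825
Maize_2,Z010,3216.048,0.479,1.071,2572.810,0.622,0.971
Maize_2,Z011,7317.351,0.408,1.511,5371.310,0.554,1.263
Soybean_4,18,68070.522,0.815,0.704,68317.303,0.823,0.607
Soybean_4,39,143007.765,0.831,0.556,148089.245,0.831,0.636
Soybean_4,40,74413.189,0.856,0.622,46240.386,0.865,0.606
Soybean_4,41,111374.677,0.809,0.544,94994.783,0.824,0.527
Soybean_4,42,182961.181,0.754,0.747,122794.534,0.800,0.566
Soybean_4,46,96267.088,0.789,0.598,73260.793,0.800,0.590
Soybean_4,48,82289.105,0.723,0.681,52981.294,0.780,0.600
Soybean_4,50,162327.393,0.779,0.601,82244.828,0.804,0.618
Soybean_4,54,150133.279,0.782,0.680,99797.457,0.818,0.563
Soybean_4,64,315164.344,0.869,0.882,235267.795,0.867,0.765
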