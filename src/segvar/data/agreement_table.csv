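image_id,annotator,variant,iou,dsc,hd
1,An1,Seg,0.952,0.976,14.765
1,An1,BBox,0.954,0.976,8.544
1,An2,Seg,0.875,0.933,43.000
1,An2,BBox,0.862,0.926,36.620
1,An3,Seg,0.941,0.970,14.142
1,An3,BBox,0.971,0.985,5.000
2,An1,Seg,0.908,0.952,22.204
2,An1,BBox,0.962,0.981,4.123
2,An2,Seg,0.911,0.954,25.000
2,An2,BBox,0.957,0.978,5.000
2,An3,Seg,0.880,0.936,52.802
2,An3,BBox,0.847,0.917,46.271
3,An1,Seg,0.888,0.941,33.734
3,An1,BBox,0.907,0.951,16.492
3,An2,Seg,0.906,0.951,32.558
3,An2,BBox,0.914,0.955,14.142
3,An3,Seg,0.891,0.943,23.324
3,An3,BBox,0.955,0.977,9.220
4,An1,Seg,0.902,0.948,29.069
4,An1,BBox,0.926,0.962,8.246
4,An2,Seg,0.848,0.918,42.438
4,An2,BBox,0.886,0.940,33.061
4,An3,Seg,0.389,0.560,371.389
4,An3,BBox,0.230,0.374,379.120
5,An1,Seg,0.905,0.950,51.614
5,An1,BBox,0.940,0.969,13.153
5,An2,Seg,0.856,0.923,57.245
5,An2,BBox,0.912,0.954,19.416
5,An3,Seg,0.893,0.943,40.162
5,An3,BBox,0.856,0.922,23.345
6,An1,Seg,0.570,0.726,162.926
6,An1,BBox,0.536,0.698,163.515
6,An2,Seg,0.811,0.895,56.223
6,An2,BBox,0.854,0.921,35.511
6,An3,Seg,0.876,0.934,52.924
6,An3,BBox,0.893,0.943,17.804
7,An1,Seg,0.578,0.733,74.632
7,An1,BBox,0.734,0.846,40.311
7,An2,Seg,0.781,0.877,32.650
7,An2,BBox,0.916,0.956,7.280
7,An3,Seg,0.819,0.901,42.579
7,An3,BBox,0.940,0.969,6.000
8,An1,Seg,0.889,0.941,52.000
8,An1,BBox,0.863,0.927,48.010
8,An2,Seg,0.957,0.978,33.121
8,An2,BBox,0.954,0.977,7.616
8,An3,Seg,0.965,0.982,28.636
8,An3,BBox,0.971,0.985,6.403
9,An1,Seg,0.591,0.743,137.773
9,An1,BBox,0.830,0.907,49.477
9,An2,Seg,0.693,0.819,74.686
9,An2,BBox,0.746,0.854,47.265
9,An3,Seg,0.679,0.809,79.202
9,An3,BBox,0.724,0.840,48.836
10,An1,Seg,0.902,0.948,25.807
10,An1,BBox,0.960,0.980,4.243
10,An2,Seg,0.788,0.881,55.803
10,An2,BBox,0.733,0.846,44.598
10,An3,Seg,0.913,0.955,18.682
10,An3,BBox,0.943,0.971,6.403
11,An1,Seg,0.644,0.783,117.652
11,An1,BBox,0.581,0.735,119.620
11,An2,Seg,0.800,0.889,362.627
11,An2,BBox,0.919,0.958,15.000
11,An3,Seg,0.670,0.803,138.105
11,An3,BBox,0.777,0.875,69.231
12,An1,Seg,0.833,0.909,66.000
12,An1,BBox,0.776,0.874,70.000
12,An2,Seg,0.872,0.932,68.447
12,An2,BBox,0.887,0.940,47.170
12,An3,Seg,0.923,0.960,43.600
12,An3,BBox,0.976,0.988,7.071
13,An1,Seg,0.823,0.903,46.174
13,An1,BBox,0.816,0.899,28.844
13,An2,Seg,0.809,0.895,62.000
13,An2,BBox,0.843,0.915,30.000
13,An3,Seg,0.865,0.928,40.522
13,An3,BBox,0.870,0.931,23.324
14,An1,Seg,0.265,0.419,331.724
14,An1,BBox,0.217,0.357,341.264
14,An2,Seg,0.219,0.359,329.524
14,An2,BBox,0.199,0.332,336.265
14,An3,Seg,0.206,0.342,331.965
14,An3,BBox,0.199,0.333,345.307
15,An1,Seg,0.130,0.230,263.610
15,An1,BBox,0.148,0.257,294.703
15,An2,Seg,0.125,0.221,218.563
15,An2,BBox,0.159,0.275,247.746
15,An3,Seg,0.129,0.228,254.342
15,An3,BBox,0.143,0.251,288.043
16,An1,Seg,0.885,0.939,36.770
16,An1,BBox,0.903,0.949,36.000
16,An2,Seg,0.809,0.894,81.006
16,An2,BBox,0.855,0.922,44.000
16,An3,Seg,0.802,0.890,90.554
16,An3,BBox,0.763,0.865,68.710
17,An1,Seg,0.706,0.828,309.015
17,An1,BBox,0.702,0.825,110.000
17,An2,Seg,0.548,0.708,330.510
17,An2,BBox,0.649,0.787,102.000
17,An3,Seg,0.616,0.762,377.922
17,An3,BBox,0.780,0.876,62.169
18,An1,Seg,0.168,0.287,429.439
18,An1,BBox,0.139,0.245,419.640
18,An2,Seg,0.167,0.286,323.303
18,An2,BBox,0.172,0.293,328.056
18,An3,Seg,0.083,0.154,404.901
18,An3,BBox,0.078,0.145,524.675
19,An1,Seg,0.901,0.948,27.295
19,An1,BBox,0.875,0.933,23.000
19,An2,Seg,0.790,0.883,58.052
19,An2,BBox,0.805,0.892,36.401
19,An3,Seg,0.835,0.910,419.715
19,An3,BBox,0.616,0.762,112.058
20,An1,Seg,0.956,0.977,30.887
20,An1,BBox,0.943,0.971,23.000
20,An2,Seg,0.870,0.930,64.938
20,An2,BBox,0.819,0.901,58.694
20,An3,Seg,0.839,0.912,87.727
20,An3,BBox,0.747,0.855,84.000
21,An1,Seg,0.873,0.932,42.012
21,An1,BBox,0.902,0.948,15.000
21,An2,Seg,0.452,0.623,119.549
21,An2,BBox,0.475,0.644,111.973
21,An3,Seg,0.853,0.920,33.377
21,An3,BBox,0.881,0.937,14.866
22,An1,Seg,0.849,0.918,68.447
22,An1,BBox,0.850,0.919,28.425
22,An2,Seg,0.854,0.921,70.264
22,An2,BBox,0.888,0.940,25.000
22,An3,Seg,0.876,0.934,43.600
22,An3,BBox,0.877,0.934,24.000
23,An1,Seg,0.402,0.573,415.473
23,An1,BBox,0.208,0.345,290.493
23,An2,Seg,0.624,0.769,57.079
23,An2,BBox,0.746,0.854,44.721
23,An3,Seg,0.534,0.696,415.120
23,An3,BBox,0.233,0.378,302.154
24,An1,Seg,0.743,0.853,71.007
24,An1,BBox,0.785,0.880,48.703
24,An2,Seg,0.632,0.775,89.022
24,An2,BBox,0.723,0.839,63.789
24,An3,Seg,0.694,0.820,80.000
24,An3,BBox,0.740,0.850,53.488
25,An1,Seg,0.838,0.912,56.511
25,An1,BBox,0.883,0.938,20.809
25,An2,Seg,0.904,0.950,22.627
25,An2,BBox,0.919,0.958,14.213
25,An3,Seg,0.751,0.858,63.600
25,An3,BBox,0.744,0.853,35.468
26,An1,Seg,0.619,0.765,156.259
26,An1,BBox,0.773,0.872,45.188
26,An2,Seg,0.561,0.718,171.047
26,An2,BBox,0.698,0.822,70.767
26,An3,Seg,0.572,0.728,175.026
26,An3,BBox,0.707,0.829,57.271
27,An1,Seg,0.873,0.932,15.000
27,An1,BBox,0.857,0.923,10.440
27,An2,Seg,0.813,0.897,24.000
27,An2,BBox,0.764,0.866,24.413
27,An3,Seg,0.804,0.891,29.547
27,An3,BBox,0.836,0.911,21.024
28,An1,Seg,0.803,0.891,34.670
28,An1,BBox,0.874,0.933,30.067
28,An2,Seg,0.773,0.872,36.056
28,An2,BBox,0.832,0.908,30.017
28,An3,Seg,0.756,0.861,35.228
28,An3,BBox,0.908,0.952,13.601
29,An1,Seg,0.791,0.883,53.254
29,An1,BBox,0.867,0.929,38.949
29,An2,Seg,0.620,0.766,180.049
29,An2,BBox,0.754,0.859,79.649
29,An3,Seg,0.622,0.767,171.234
29,An3,BBox,0.807,0.893,54.406
30,An1,Seg,0.821,0.902,67.231
30,An1,BBox,0.810,0.895,40.792
30,An2,Seg,0.878,0.935,26.926
30,An2,BBox,0.816,0.899,27.731
30,An3,Seg,0.832,0.908,59.641
30,An3,BBox,0.879,0.936,24.739
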