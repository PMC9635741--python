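age,sex,q_annual
30,female,0.000494
30,male,0.000659
31,female,0.000539
31,male,0.000718
32,female,0.000588
32,male,0.000783
33,female,0.000641
33,male,0.000854
34,female,0.000699
34,male,0.000932
35,female,0.000762
35,male,0.001016
36,female,0.000831
36,male,0.001108
37,female,0.000906
37,male,0.001208
38,female,0.000988
38,male,0.001317
39,female,0.001078
39,male,0.001436
40,female,0.001175
40,male,0.001566
41,female,0.001281
41,male,0.001708
42,female,0.001397
42,male,0.001862
43,female,0.001524
43,male,0.002031
44,female,0.001661
44,male,0.002214
45,female,0.001812
45,male,0.002415
46,female,0.001975
46,male,0.002633
47,female,0.002154
47,male,0.002871
48,female,0.002349
48,male,0.00313
49,female,0.002561
49,male,0.003413
50,female,0.002792
50,male,0.003721
51,female,0.003045
51,male,0.004058
52,female,0.00332
52,male,0.004424
53,female,0.00362
53,male,0.004823
54,female,0.003947
54,male,0.005259
55,female,0.004303
55,male,0.005734
56,female,0.004692
56,male,0.006251
57,female,0.005115
57,male,0.006815
58,female,0.005577
58,male,0.007429
59,female,0.00608
59,male,0.008099
60,female,0.006629
60,male,0.008829
61,female,0.007226
61,male,0.009624
62,female,0.007878
62,male,0.01049
63,female,0.008588
63,male,0.011434
64,female,0.009362
64,male,0.012463
65,female,0.010204
65,male,0.013583
66,female,0.011123
66,male,0.014803
67,female,0.012124
67,male,0.016132
68,female,0.013213
68,male,0.017579
69,female,0.014401
69,male,0.019155
70,female,0.015694
70,male,0.02087
71,female,0.017102
71,male,0.022738
72,female,0.018635
72,male,0.02477
73,female,0.020305
73,male,0.026981
74,female,0.022122
74,male,0.029387
75,female,0.0241
75,male,0.032004
76,female,0.026252
76,male,0.034849
77,female,0.028594
77,male,0.037943
78,female,0.031141
78,male,0.041305
79,female,0.033912
79,male,0.044958
80,female,0.036924
80,male,0.048926
81,female,0.040197
81,male,0.053234
82,female,0.043755
82,male,0.05791
83,female,0.047619
83,male,0.062983
84,female,0.051816
84,male,0.068484
85,female,0.056371
85,male,0.074446
86,female,0.061313
86,male,0.080904
87,female,0.066673
87,male,0.087895
88,female,0.072484
88,male,0.095458
89,female,0.078779
89,male,0.103635
90,female,0.085595
90,male,0.112467
91,female,0.092971
91,male,0.121999
92,female,0.100946
92,male,0.132278
93,female,0.109564
93,male,0.143349
94,female,0.118867
94,male,0.155262
95,female,0.128901
95,male,0.168064
96,female,0.139714
96,male,0.181804
97,female,0.151352
97,male,0.196529
98,female,0.163864
98,male,0.212285
99,female,0.177298
99,male,0.229114
100,female,0.191702
100,male,0.247058
101,female,0.207123
101,male,0.266149
102,female,0.223604
102,male,0.286418
103,female,0.241187
103,male,0.307883
104,female,0.259908
104,male,0.330555
105,female,0.279796
105,male,0.354434
106,female,0.300876
106,male,0.379505
107,female,0.323162
107,male,0.405735
108,female,0.346655
108,male,0.433078
109,female,0.371346
109,male,0.461463
110,female,1.0
110,male,1.0
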