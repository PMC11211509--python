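pct_stride,hip_deg,knee_deg,ankle_deg
0.0,35.0,6.38,0.09
1.0,35.94,6.75,0.42
2.0,36.75,7.22,0.76
3.0,37.41,7.77,1.1
4.0,37.91,8.42,1.43
5.0,38.23,9.15,1.77
6.0,38.37,9.95,2.11
7.0,38.31,10.8,2.45
8.0,38.04,11.69,2.79
9.0,37.57,12.6,3.13
10.0,36.88,13.49,3.46
11.0,35.97,14.35,3.8
12.0,34.85,15.17,4.13
13.0,33.52,15.91,4.47
14.0,31.98,16.56,4.8
15.0,30.24,17.12,5.13
16.0,28.31,17.58,5.46
17.0,26.21,17.94,5.78
18.0,23.94,18.2,6.11
19.0,21.52,18.38,6.43
20.0,18.97,18.49,6.75
21.0,16.31,18.55,7.07
22.0,13.57,18.58,7.38
23.0,10.75,18.6,7.69
24.0,7.89,18.62,7.99
25.0,5.0,18.66,8.29
26.0,2.11,18.74,8.58
27.0,-0.75,18.85,8.85
28.0,-3.57,19.01,9.12
29.0,-6.31,19.22,9.37
30.0,-8.97,19.48,9.61
31.0,-11.52,19.78,9.82
32.0,-13.94,20.11,10.02
33.0,-16.21,20.48,10.19
34.0,-18.31,20.87,10.33
35.0,-20.24,21.28,10.44
36.0,-21.98,21.71,10.52
37.0,-23.52,22.14,10.55
38.0,-24.85,22.57,10.55
39.0,-25.97,23.01,10.49
40.0,-26.88,23.45,10.38
41.0,-27.57,23.89,10.2
42.0,-28.04,24.35,9.95
43.0,-28.31,24.81,9.61
44.0,-28.37,25.3,9.16
45.0,-28.23,25.82,8.6
46.0,-27.91,26.39,7.91
47.0,-27.41,27.02,7.05
48.0,-26.75,27.73,6.03
49.0,-25.94,28.53,4.83
50.0,-25.0,29.45,3.43
51.0,-23.94,30.49,1.83
52.0,-22.77,31.69,0.06
53.0,-21.52,33.05,-1.87
54.0,-20.2,34.58,-3.93
55.0,-18.83,36.3,-6.06
56.0,-17.42,38.2,-8.19
57.0,-15.98,40.28,-10.27
58.0,-14.53,42.53,-12.2
59.0,-13.09,44.92,-13.92
60.0,-11.66,47.43,-15.37
61.0,-10.26,50.01,-16.48
62.0,-8.88,52.62,-17.21
63.0,-7.55,55.19,-17.57
64.0,-6.26,57.68,-17.55
65.0,-5.03,60.01,-17.18
66.0,-3.84,62.12,-16.51
67.0,-2.7,63.94,-15.6
68.0,-1.61,65.41,-14.52
69.0,-0.57,66.48,-13.34
70.0,0.43,67.1,-12.13
71.0,1.39,67.24,-10.94
72.0,2.32,66.87,-9.82
73.0,3.23,66.0,-8.8
74.0,4.12,64.64,-7.9
75.0,5.0,62.8,-7.13
76.0,5.88,60.53,-6.48
77.0,6.77,57.87,-5.95
78.0,7.68,54.89,-5.52
79.0,8.61,51.65,-5.17
80.0,9.57,48.22,-4.89
81.0,10.57,44.67,-4.65
82.0,11.61,41.07,-4.45
83.0,12.7,37.49,-4.26
84.0,13.84,33.98,-4.08
85.0,15.03,30.6,-3.9
86.0,16.26,27.39,-3.71
87.0,17.55,24.39,-3.52
88.0,18.88,21.61,-3.31
89.0,20.26,19.08,-3.09
90.0,21.66,16.8,-2.86
91.0,23.09,14.78,-2.61
92.0,24.53,13.0,-2.35
93.0,25.98,11.46,-2.08
94.0,27.42,10.15,-1.8
95.0,28.83,9.04,-1.51
96.0,30.2,8.12,-1.22
97.0,31.52,7.37,-0.92
98.0,32.77,6.78,-0.61
99.0,33.94,6.33,-0.3
100.0,35.0,5.99,0.01
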