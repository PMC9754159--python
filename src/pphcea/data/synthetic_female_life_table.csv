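age,remaining_life_expectancy
0.0,87.7
1.0,86.66
2.0,85.62
3.0,84.58
4.0,83.55
5.0,82.52
6.0,81.5
7.0,80.47
8.0,79.45
9.0,78.43
10.0,77.42
11.0,76.41
12.0,75.4
13.0,74.4
14.0,73.39
15.0,72.4
16.0,71.4
17.0,70.41
18.0,69.42
19.0,68.43
20.0,67.45
21.0,66.47
22.0,65.5
23.0,64.53
24.0,63.56
25.0,62.59
26.0,61.63
27.0,60.67
28.0,59.72
29.0,58.77
30.0,57.82
31.0,56.88
32.0,55.94
33.0,55.0
34.0,54.07
35.0,53.14
36.0,52.21
37.0,51.29
38.0,50.38
39.0,49.46
40.0,48.55
41.0,47.65
42.0,46.75
43.0,45.85
44.0,44.96
45.0,44.07
46.0,43.18
47.0,42.3
48.0,41.43
49.0,40.55
50.0,39.69
51.0,38.82
52.0,37.96
53.0,37.11
54.0,36.26
55.0,35.42
56.0,34.58
57.0,33.74
58.0,32.91
59.0,32.09
60.0,31.26
61.0,30.45
62.0,29.64
63.0,28.83
64.0,28.03
65.0,27.24
66.0,26.45
67.0,25.67
68.0,24.89
69.0,24.12
70.0,23.35
71.0,22.59
72.0,21.83
73.0,21.09
74.0,20.34
75.0,19.61
76.0,18.88
77.0,18.15
78.0,17.44
79.0,16.73
80.0,16.03
81.0,15.33
82.0,14.64
83.0,13.96
84.0,13.29
85.0,12.63
86.0,11.97
87.0,11.32
88.0,10.68
89.0,10.05
90.0,9.43
91.0,8.82
92.0,8.22
93.0,7.62
94.0,7.04
95.0,6.47
96.0,5.91
97.0,5.37
98.0,4.83
99.0,4.31
100.0,3.81
101.0,3.32
102.0,2.84
103.0,2.39
104.0,1.95
105.0,1.54
106.0,1.15
107.0,0.79
108.0,0.46
109.0,0.19
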