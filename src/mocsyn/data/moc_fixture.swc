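# SWC export; columns: id type x y z radius parent
1 1 0.0000 0.0000 0.0 3.0500 -1
2 1 33.6000 0.0000 0.0 3.0500 1
3 2 0.0000 1.0000 0.0 0.5000 2
4 2 180.0000 1.0000 0.0 0.5000 3
5 3 0.0000 2.0000 0.0 0.5000 2
6 3 12.8000 2.0000 0.0 0.5000 5
7 3 0.0000 3.0000 0.0 0.5000 2
8 3 10.1000 3.0000 0.0 0.5000 7
9 3 0.0000 4.0000 0.0 0.5000 2
10 3 7.3000 4.0000 0.0 0.5000 9
11 3 0.0000 5.0000 0.0 0.5000 6
12 3 1.5000 5.0000 0.0 0.5000 11
13 3 0.0000 6.0000 0.0 0.5111 6
14 3 2.1644 6.0000 0.0 0.5111 13
15 3 0.0000 7.0000 0.0 0.5222 6
16 3 2.8289 7.0000 0.0 0.5222 15
17 3 0.0000 8.0000 0.0 0.5333 6
18 3 3.4933 8.0000 0.0 0.5333 17
19 3 0.0000 9.0000 0.0 0.5444 6
20 3 4.1578 9.0000 0.0 0.5444 19
21 3 0.0000 10.0000 0.0 0.5556 6
22 3 4.8222 10.0000 0.0 0.5556 21
23 3 0.0000 11.0000 0.0 0.5667 6
24 3 5.4867 11.0000 0.0 0.5667 23
25 3 0.0000 12.0000 0.0 0.5778 6
26 3 6.1511 12.0000 0.0 0.5778 25
27 3 0.0000 13.0000 0.0 0.5889 6
28 3 6.8156 13.0000 0.0 0.5889 27
29 3 0.0000 14.0000 0.0 0.6000 6
30 3 7.4800 14.0000 0.0 0.6000 29
31 3 0.0000 15.0000 0.0 0.6111 6
32 3 8.1444 15.0000 0.0 0.6111 31
33 3 0.0000 16.0000 0.0 0.6222 6
34 3 8.8089 16.0000 0.0 0.6222 33
35 3 0.0000 17.0000 0.0 0.6333 6
36 3 9.4733 17.0000 0.0 0.6333 35
37 3 0.0000 18.0000 0.0 0.6444 6
38 3 10.1378 18.0000 0.0 0.6444 37
39 3 0.0000 19.0000 0.0 0.6556 6
40 3 10.8022 19.0000 0.0 0.6556 39
41 3 0.0000 20.0000 0.0 0.6667 6
42 3 11.4667 20.0000 0.0 0.6667 41
43 3 0.0000 21.0000 0.0 0.6778 6
44 3 12.1311 21.0000 0.0 0.6778 43
45 3 0.0000 22.0000 0.0 0.6889 6
46 3 12.7956 22.0000 0.0 0.6889 45
47 3 0.0000 23.0000 0.0 0.7000 6
48 3 13.4600 23.0000 0.0 0.7000 47
49 3 0.0000 24.0000 0.0 0.7111 6
50 3 14.1244 24.0000 0.0 0.7111 49
51 3 0.0000 25.0000 0.0 0.7222 6
52 3 14.7889 25.0000 0.0 0.7222 51
53 3 0.0000 26.0000 0.0 0.7333 6
54 3 15.4533 26.0000 0.0 0.7333 53
55 3 0.0000 27.0000 0.0 0.7444 6
56 3 16.1178 27.0000 0.0 0.7444 55
57 3 0.0000 28.0000 0.0 0.7556 6
58 3 16.7822 28.0000 0.0 0.7556 57
59 3 0.0000 29.0000 0.0 0.7667 6
60 3 17.4467 29.0000 0.0 0.7667 59
61 3 0.0000 30.0000 0.0 0.7778 6
62 3 18.1111 30.0000 0.0 0.7778 61
63 3 0.0000 31.0000 0.0 0.7889 6
64 3 18.7756 31.0000 0.0 0.7889 63
65 3 0.0000 32.0000 0.0 0.8000 6
66 3 19.4400 32.0000 0.0 0.8000 65
67 3 0.0000 33.0000 0.0 0.8111 6
68 3 20.1044 33.0000 0.0 0.8111 67
69 3 0.0000 34.0000 0.0 0.8222 6
70 3 20.7689 34.0000 0.0 0.8222 69
71 3 0.0000 35.0000 0.0 0.8333 6
72 3 21.4333 35.0000 0.0 0.8333 71
73 3 0.0000 36.0000 0.0 0.8444 6
74 3 22.0978 36.0000 0.0 0.8444 73
75 3 0.0000 37.0000 0.0 0.8556 6
76 3 22.7622 37.0000 0.0 0.8556 75
77 3 0.0000 38.0000 0.0 0.8667 6
78 3 23.4267 38.0000 0.0 0.8667 77
79 3 0.0000 39.0000 0.0 0.8778 6
80 3 24.0911 39.0000 0.0 0.8778 79
81 3 0.0000 40.0000 0.0 0.8889 6
82 3 24.7556 40.0000 0.0 0.8889 81
83 3 0.0000 41.0000 0.0 0.9000 6
84 3 25.4200 41.0000 0.0 0.9000 83
85 3 0.0000 42.0000 0.0 0.9111 6
86 3 26.0844 42.0000 0.0 0.9111 85
87 3 0.0000 43.0000 0.0 0.9222 6
88 3 26.7489 43.0000 0.0 0.9222 87
89 3 0.0000 44.0000 0.0 0.9333 6
90 3 27.4133 44.0000 0.0 0.9333 89
91 3 0.0000 45.0000 0.0 0.9444 6
92 3 28.0778 45.0000 0.0 0.9444 91
93 3 0.0000 46.0000 0.0 0.9556 6
94 3 28.7422 46.0000 0.0 0.9556 93
95 3 0.0000 47.0000 0.0 0.9667 6
96 3 29.4067 47.0000 0.0 0.9667 95
97 3 0.0000 48.0000 0.0 0.9778 6
98 3 30.0711 48.0000 0.0 0.9778 97
99 3 0.0000 49.0000 0.0 0.9889 6
100 3 30.7356 49.0000 0.0 0.9889 99
101 3 0.0000 50.0000 0.0 1.0000 6
102 3 31.4000 50.0000 0.0 1.0000 101
103 3 0.0000 51.0000 0.0 0.5000 8
104 3 1.5000 51.0000 0.0 0.5000 103
105 3 0.0000 52.0000 0.0 0.5263 8
106 3 3.0737 52.0000 0.0 0.5263 105
107 3 0.0000 53.0000 0.0 0.5526 8
108 3 4.6474 53.0000 0.0 0.5526 107
109 3 0.0000 54.0000 0.0 0.5789 8
110 3 6.2211 54.0000 0.0 0.5789 109
111 3 0.0000 55.0000 0.0 0.6053 8
112 3 7.7947 55.0000 0.0 0.6053 111
113 3 0.0000 56.0000 0.0 0.6316 8
114 3 9.3684 56.0000 0.0 0.6316 113
115 3 0.0000 57.0000 0.0 0.6579 8
116 3 10.9421 57.0000 0.0 0.6579 115
117 3 0.0000 58.0000 0.0 0.6842 8
118 3 12.5158 58.0000 0.0 0.6842 117
119 3 0.0000 59.0000 0.0 0.7105 8
120 3 14.0895 59.0000 0.0 0.7105 119
121 3 0.0000 60.0000 0.0 0.7368 8
122 3 15.6632 60.0000 0.0 0.7368 121
123 3 0.0000 61.0000 0.0 0.7632 8
124 3 17.2368 61.0000 0.0 0.7632 123
125 3 0.0000 62.0000 0.0 0.7895 8
126 3 18.8105 62.0000 0.0 0.7895 125
127 3 0.0000 63.0000 0.0 0.8158 8
128 3 20.3842 63.0000 0.0 0.8158 127
129 3 0.0000 64.0000 0.0 0.8421 8
130 3 21.9579 64.0000 0.0 0.8421 129
131 3 0.0000 65.0000 0.0 0.8684 8
132 3 23.5316 65.0000 0.0 0.8684 131
133 3 0.0000 66.0000 0.0 0.8947 8
134 3 25.1053 66.0000 0.0 0.8947 133
135 3 0.0000 67.0000 0.0 0.9211 8
136 3 26.6789 67.0000 0.0 0.9211 135
137 3 0.0000 68.0000 0.0 0.9474 8
138 3 28.2526 68.0000 0.0 0.9474 137
139 3 0.0000 69.0000 0.0 0.9737 8
140 3 29.8263 69.0000 0.0 0.9737 139
141 3 0.0000 70.0000 0.0 1.0000 8
142 3 31.4000 70.0000 0.0 1.0000 141
143 3 0.0000 71.0000 0.0 0.5000 10
144 3 1.5000 71.0000 0.0 0.5000 143
145 3 0.0000 72.0000 0.0 0.5714 10
146 3 5.7714 72.0000 0.0 0.5714 145
147 3 0.0000 73.0000 0.0 0.6429 10
148 3 10.0429 73.0000 0.0 0.6429 147
149 3 0.0000 74.0000 0.0 0.7143 10
150 3 14.3143 74.0000 0.0 0.7143 149
151 3 0.0000 75.0000 0.0 0.7857 10
152 3 18.5857 75.0000 0.0 0.7857 151
153 3 0.0000 76.0000 0.0 0.8571 10
154 3 22.8571 76.0000 0.0 0.8571 153
155 3 0.0000 77.0000 0.0 0.9286 10
156 3 27.1286 77.0000 0.0 0.9286 155
157 3 0.0000 78.0000 0.0 1.0000 10
158 3 31.4000 78.0000 0.0 1.0000 157
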