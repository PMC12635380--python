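index,r,g,b
0,68,1,84
1,68,2,86
2,69,4,87
3,69,5,89
4,70,7,90
5,70,8,92
6,70,10,93
7,70,11,94
8,71,13,96
9,71,14,97
10,71,16,99
11,71,17,100
12,71,19,101
13,72,20,103
14,72,22,104
15,72,23,105
16,72,24,106
17,72,26,108
18,72,27,109
19,72,28,110
20,72,29,111
21,72,31,112
22,72,32,113
23,72,33,115
24,72,35,116
25,72,36,117
26,72,37,118
27,72,38,119
28,72,40,120
29,72,41,121
30,71,42,122
31,71,44,122
32,71,45,123
33,71,46,124
34,71,47,125
35,70,48,126
36,70,50,126
37,70,51,127
38,70,52,128
39,69,53,129
40,69,55,129
41,69,56,130
42,68,57,131
43,68,58,131
44,68,59,132
45,67,61,132
46,67,62,133
47,66,63,133
48,66,64,134
49,66,65,134
50,65,66,135
51,65,68,135
52,64,69,136
53,64,70,136
54,63,71,136
55,63,72,137
56,62,73,137
57,62,74,137
58,62,76,138
59,61,77,138
60,61,78,138
61,60,79,138
62,60,80,139
63,59,81,139
64,59,82,139
65,58,83,139
66,58,84,140
67,57,85,140
68,57,86,140
69,56,88,140
70,56,89,140
71,55,90,140
72,55,91,141
73,54,92,141
74,54,93,141
75,53,94,141
76,53,95,141
77,52,96,141
78,52,97,141
79,51,98,141
80,51,99,141
81,50,100,142
82,50,101,142
83,49,102,142
84,49,103,142
85,49,104,142
86,48,105,142
87,48,106,142
88,47,107,142
89,47,108,142
90,46,109,142
91,46,110,142
92,46,111,142
93,45,112,142
94,45,113,142
95,44,113,142
96,44,114,142
97,44,115,142
98,43,116,142
99,43,117,142
100,42,118,142
101,42,119,142
102,42,120,142
103,41,121,142
104,41,122,142
105,41,123,142
106,40,124,142
107,40,125,142
108,39,126,142
109,39,127,142
110,39,128,142
111,38,129,142
112,38,130,142
113,38,130,143
114,37,131,142
115,37,132,142
116,37,133,142
117,36,134,142
118,36,135,142
119,35,136,142
120,35,137,142
121,35,138,141
122,34,139,141
123,34,140,141
124,34,141,141
125,33,142,141
126,33,143,141
127,33,144,141
128,33,145,140
129,32,146,140
130,32,146,141
131,32,147,140
132,31,148,140
133,31,149,139
134,31,150,139
135,31,151,139
136,31,152,139
137,31,153,138
138,31,154,138
139,30,155,138
140,30,156,137
141,30,157,137
142,31,158,137
143,31,159,136
144,31,160,136
145,31,161,136
146,31,161,135
147,31,162,135
148,32,163,134
149,32,164,134
150,33,165,133
151,33,166,133
152,34,167,133
153,34,168,132
154,35,169,131
155,36,170,131
156,37,171,130
157,37,172,130
158,38,173,129
159,39,173,129
160,40,174,128
161,41,175,127
162,42,176,127
163,44,177,126
164,45,178,125
165,46,179,124
166,47,180,124
167,49,181,123
168,50,182,122
169,52,182,121
170,53,183,121
171,55,184,120
172,56,185,119
173,58,186,118
174,59,187,117
175,61,188,116
176,63,188,115
177,64,189,114
178,66,190,113
179,68,191,112
180,70,192,111
181,72,193,110
182,74,193,109
183,76,194,108
184,78,195,107
185,80,196,106
186,82,197,105
187,84,197,104
188,86,198,103
189,88,199,101
190,90,200,100
191,92,200,99
192,94,201,98
193,96,202,96
194,99,203,95
195,101,203,94
196,103,204,92
197,105,205,91
198,108,205,90
199,110,206,88
200,112,207,87
201,115,208,86
202,117,208,84
203,119,209,83
204,122,209,81
205,124,210,80
206,127,211,78
207,129,211,77
208,132,212,75
209,134,213,73
210,137,213,72
211,139,214,70
212,142,214,69
213,144,215,67
214,147,215,65
215,149,216,64
216,152,216,62
217,155,217,60
218,157,217,59
219,160,218,57
220,162,218,55
221,165,219,54
222,168,219,52
223,170,220,50
224,173,220,48
225,176,221,47
226,178,221,45
227,181,222,43
228,184,222,41
229,186,222,40
230,189,223,38
231,192,223,37
232,194,223,35
233,197,224,33
234,200,224,32
235,202,225,31
236,205,225,29
237,208,225,28
238,210,226,27
239,213,226,26
240,216,226,25
241,218,227,25
242,221,227,24
243,223,227,24
244,226,228,24
245,229,228,25
246,231,228,25
247,234,229,26
248,236,229,27
249,239,229,28
250,241,229,29
251,244,230,30
252,246,230,32
253,248,230,33
254,251,231,35
255,253,231,37
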