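roi_id	roi_name	hemisphere	network
1	VIS_1_L	L	visual
2	VIS_1_R	R	visual
3	VIS_2_L	L	visual
4	VIS_2_R	R	visual
5	VIS_3_L	L	visual
6	VIS_3_R	R	visual
7	VIS_4_L	L	visual
8	VIS_4_R	R	visual
9	VIS_5_L	L	visual
10	VIS_5_R	R	visual
11	VIS_6_L	L	visual
12	VIS_6_R	R	visual
13	VIS_7_L	L	visual
14	VIS_7_R	R	visual
15	VIS_8_L	L	visual
16	VIS_8_R	R	visual
17	VIS_9_L	L	visual
18	VIS_9_R	R	visual
19	VIS_10_L	L	visual
20	VIS_10_R	R	visual
21	VIS_11_L	L	visual
22	VIS_11_R	R	visual
23	VIS_12_L	L	visual
24	VIS_12_R	R	visual
25	VIS_13_L	L	visual
26	VIS_13_R	R	visual
27	VIS_14_L	L	visual
28	VIS_14_R	R	visual
29	VIS_15_L	L	visual
30	VIS_15_R	R	visual
31	SM_1_L	L	somatomotor
32	SM_1_R	R	somatomotor
33	SM_2_L	L	somatomotor
34	SM_2_R	R	somatomotor
35	SM_3_L	L	somatomotor
36	SM_3_R	R	somatomotor
37	SM_4_L	L	somatomotor
38	SM_4_R	R	somatomotor
39	SM_5_L	L	somatomotor
40	SM_5_R	R	somatomotor
41	SM_6_L	L	somatomotor
42	SM_6_R	R	somatomotor
43	SM_7_L	L	somatomotor
44	SM_7_R	R	somatomotor
45	SM_8_L	L	somatomotor
46	SM_8_R	R	somatomotor
47	SM_9_L	L	somatomotor
48	SM_9_R	R	somatomotor
49	SM_10_L	L	somatomotor
50	SM_10_R	R	somatomotor
51	SM_11_L	L	somatomotor
52	SM_11_R	R	somatomotor
53	SM_12_L	L	somatomotor
54	SM_12_R	R	somatomotor
55	SM_13_L	L	somatomotor
56	SM_13_R	R	somatomotor
57	SM_14_L	L	somatomotor
58	SM_14_R	R	somatomotor
59	SM_15_L	L	somatomotor
60	SM_15_R	R	somatomotor
61	SM_16_L	L	somatomotor
62	SM_16_R	R	somatomotor
63	SM_17_L	L	somatomotor
64	SM_17_R	R	somatomotor
65	DAN_1_L	L	dorsal_attention
66	DAN_1_R	R	dorsal_attention
67	DAN_2_L	L	dorsal_attention
68	DAN_2_R	R	dorsal_attention
69	DAN_3_L	L	dorsal_attention
70	DAN_3_R	R	dorsal_attention
71	DAN_4_L	L	dorsal_attention
72	DAN_4_R	R	dorsal_attention
73	DAN_5_L	L	dorsal_attention
74	DAN_5_R	R	dorsal_attention
75	DAN_6_L	L	dorsal_attention
76	DAN_6_R	R	dorsal_attention
77	DAN_7_L	L	dorsal_attention
78	DAN_7_R	R	dorsal_attention
79	DAN_8_L	L	dorsal_attention
80	DAN_8_R	R	dorsal_attention
81	DAN_9_L	L	dorsal_attention
82	DAN_9_R	R	dorsal_attention
83	DAN_10_L	L	dorsal_attention
84	DAN_10_R	R	dorsal_attention
85	DAN_11_L	L	dorsal_attention
86	DAN_11_R	R	dorsal_attention
87	DAN_12_L	L	dorsal_attention
88	DAN_12_R	R	dorsal_attention
89	DAN_13_L	L	dorsal_attention
90	DAN_13_R	R	dorsal_attention
91	VAN_1_L	L	ventral_attention
92	VAN_1_R	R	ventral_attention
93	VAN_2_L	L	ventral_attention
94	VAN_2_R	R	ventral_attention
95	VAN_3_L	L	ventral_attention
96	VAN_3_R	R	ventral_attention
97	VAN_4_L	L	ventral_attention
98	VAN_4_R	R	ventral_attention
99	VAN_5_L	L	ventral_attention
100	VAN_5_R	R	ventral_attention
101	VAN_6_L	L	ventral_attention
102	VAN_6_R	R	ventral_attention
103	VAN_7_L	L	ventral_attention
104	VAN_7_R	R	ventral_attention
105	VAN_8_L	L	ventral_attention
106	VAN_8_R	R	ventral_attention
107	VAN_9_L	L	ventral_attention
108	VAN_9_R	R	ventral_attention
109	VAN_10_L	L	ventral_attention
110	VAN_10_R	R	ventral_attention
111	VAN_11_L	L	ventral_attention
112	VAN_11_R	R	ventral_attention
113	VAN_12_L	L	ventral_attention
114	VAN_12_R	R	ventral_attention
115	LIM_1_L	L	limbic
116	LIM_1_R	R	limbic
117	LIM_2_L	L	limbic
118	LIM_2_R	R	limbic
119	LIM_3_L	L	limbic
120	LIM_3_R	R	limbic
121	LIM_4_L	L	limbic
122	LIM_4_R	R	limbic
123	LIM_5_L	L	limbic
124	LIM_5_R	R	limbic
125	LIM_6_L	L	limbic
126	LIM_6_R	R	limbic
127	LIM_7_L	L	limbic
128	LIM_7_R	R	limbic
129	LIM_8_L	L	limbic
130	LIM_8_R	R	limbic
131	LIM_9_L	L	limbic
132	LIM_9_R	R	limbic
133	LIM_10_L	L	limbic
134	LIM_10_R	R	limbic
135	LIM_11_L	L	limbic
136	LIM_11_R	R	limbic
137	FP_1_L	L	frontoparietal
138	FP_1_R	R	frontoparietal
139	FP_2_L	L	frontoparietal
140	FP_2_R	R	frontoparietal
141	FP_3_L	L	frontoparietal
142	FP_3_R	R	frontoparietal
143	FP_4_L	L	frontoparietal
144	FP_4_R	R	frontoparietal
145	FP_5_L	L	frontoparietal
146	FP_5_R	R	frontoparietal
147	FP_6_L	L	frontoparietal
148	FP_6_R	R	frontoparietal
149	FP_7_L	L	frontoparietal
150	FP_7_R	R	frontoparietal
151	FP_8_L	L	frontoparietal
152	FP_8_R	R	frontoparietal
153	FP_9_L	L	frontoparietal
154	FP_9_R	R	frontoparietal
155	FP_10_L	L	frontoparietal
156	FP_10_R	R	frontoparietal
157	FP_11_L	L	frontoparietal
158	FP_11_R	R	frontoparietal
159	FP_12_L	L	frontoparietal
160	FP_12_R	R	frontoparietal
161	FP_13_L	L	frontoparietal
162	FP_13_R	R	frontoparietal
163	FP_14_L	L	frontoparietal
164	FP_14_R	R	frontoparietal
165	FP_15_L	L	frontoparietal
166	FP_15_R	R	frontoparietal
167	DMN_1_L	L	default
168	DMN_1_R	R	default
169	DMN_2_L	L	default
170	DMN_2_R	R	default
171	DMN_3_L	L	default
172	DMN_3_R	R	default
173	DMN_4_L	L	default
174	DMN_4_R	R	default
175	DMN_5_L	L	default
176	DMN_5_R	R	default
177	DMN_6_L	L	default
178	DMN_6_R	R	default
179	DMN_7_L	L	default
180	DMN_7_R	R	default
181	DMN_8_L	L	default
182	DMN_8_R	R	default
183	DMN_9_L	L	default
184	DMN_9_R	R	default
185	DMN_10_L	L	default
186	DMN_10_R	R	default
187	DMN_11_L	L	default
188	DMN_11_R	R	default
189	DMN_12_L	L	default
190	DMN_12_R	R	default
191	DMN_13_L	L	default
192	DMN_13_R	R	default
193	DMN_14_L	L	default
194	DMN_14_R	R	default
195	DMN_15_L	L	default
196	DMN_15_R	R	default
197	DMN_16_L	L	default
198	DMN_16_R	R	default
199	DMN_17_L	L	default
200	DMN_17_R	R	default
201	DMN_18_L	L	default
202	DMN_18_R	R	default
203	DMN_19_L	L	default
204	DMN_19_R	R	default
205	DMN_20_L	L	default
206	DMN_20_R	R	default
207	DMN_21_L	L	default
208	DMN_21_R	R	default
209	DMN_22_L	L	default
210	DMN_22_R	R	default
211	SUB_1_L	L	subcortical
212	SUB_1_R	R	subcortical
213	SUB_2_L	L	subcortical
214	SUB_2_R	R	subcortical
215	SUB_3_L	L	subcortical
216	SUB_3_R	R	subcortical
217	SUB_4_L	L	subcortical
218	SUB_4_R	R	subcortical
219	SUB_5_L	L	subcortical
220	SUB_5_R	R	subcortical
221	SUB_6_L	L	subcortical
222	SUB_6_R	R	subcortical
223	SUB_7_L	L	subcortical
224	SUB_7_R	R	subcortical
225	SUB_8_L	L	subcortical
226	SUB_8_R	R	subcortical
227	SUB_9_L	L	subcortical
228	SUB_9_R	R	subcortical
229	SUB_10_L	L	subcortical
230	SUB_10_R	R	subcortical
231	SUB_11_L	L	subcortical
232	SUB_11_R	R	subcortical
233	SUB_12_L	L	subcortical
234	SUB_12_R	R	subcortical
235	SUB_13_L	L	subcortical
236	SUB_13_R	R	subcortical
237	SUB_14_L	L	subcortical
238	SUB_14_R	R	subcortical
239	SUB_15_L	L	subcortical
240	SUB_15_R	R	subcortical
241	SUB_16_L	L	subcortical
242	SUB_16_R	R	subcortical
243	SUB_17_L	L	subcortical
244	SUB_17_R	R	subcortical
245	SUB_18_L	L	subcortical
246	SUB_18_R	R	subcortical
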