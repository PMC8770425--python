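roi_id	name	hemisphere	network	x	y	z	radius_mm
1	Superior Frontal Gyrus (L)	L	1	0	24	50	5
2	Middle Frontal Gyrus (R)	R	1	40	24	42	5
3	Inferior Parietal Lobule (R)	R	1	58	-52	38	5
4	Inferior Parietal Lobule (L)	L	1	-58	-50	44	5
5	Middle Frontal Gyrus (L)	L	1	-36	52	-2	5
6	Middle Frontal Gyrus (L)	L	1	-42	14	48	5
7	Middle Frontal Gyrus (R)	R	1	42	46	-8	5
8	Insula (R)	R	1	36	16	6	5
9	Cingulate Gyrus (R)	R	1	2	-22	30	5
10	Precuneus (R)	R	1	10	-64	36	5
11	Inferior Frontal Gyrus (L)	L	2	-46	24	-8	5
12	Superior Frontal Gyrus (L)	L	2	-4	10	62	5
13	Inferior Frontal Gyrus (R)	R	2	50	28	-8	5
14	Superior Temporal Gyrus (L)	L	2	-46	-52	28	5
15	Middle Temporal Gyrus (L)	L	2	-54	-34	-2	5
16	Middle Frontal Gyrus (L)	L	2	-44	6	50	5
17	Superior Frontal Gyrus (L)	L	2	-30	48	26	5
18	Caudate (L)	L	2	-16	10	12	5
19	Tuber (R)	R	2	36	-60	-30	5
20	Amygdala (L)	L	3	-22	-4	-16	5
21	Amygdala (R)	R	3	24	-4	-18	5
22	Fusiform Gyrus (R)	R	3	40	-46	-18	5
23	Thalamus (R)	R	3	6	-26	0	5
24	Fusiform Gyrus (L)	L	3	-38	-54	-14	5
25	Parahippocampal Gyrus (L)	L	3	-22	-28	-4	5
26	Medial Frontal Gyrus (B)	B	3	0	54	-10	5
27	Inferior Occipital Gyrus (L)	L	3	-42	-76	-6	5
28	Postcentral Gyrus (L)	L	4	-58	-22	32	5
29	Insula (L)	L	4	-44	-4	10	5
30	Superior Parietal Lobule (L)	L	4	-28	-52	56	5
31	Postcentral Gyrus (R)	R	4	62	-22	30	5
32	Cuneus (L)	L	4	-10	-76	22	5
33	Middle Occipital Gyrus (L)	L	4	-48	-74	2	5
34	Thalamus (R)	R	4	10	-26	-4	5
35	Precuneus (R)	R	4	28	-60	38	5
36	Posterior Cingulate (R)	R	4	16	-56	16	5
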