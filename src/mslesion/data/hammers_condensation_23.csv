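subregion_label,key_area_name
1,hippocampus
2,hippocampus
3,amygdala
4,amygdala
5,temporal lobe
6,temporal lobe
7,temporal lobe
8,temporal lobe
9,parahippocampal gyrus
10,parahippocampal gyrus
11,temporal lobe
12,temporal lobe
13,temporal lobe
14,temporal lobe
15,temporal lobe
16,temporal lobe
17,cerebellum
18,cerebellum
19,brainstem
20,insula
21,insula
22,occipital lobe
23,occipital lobe
24,cingulum
25,cingulum
26,cingulum
27,cingulum
28,frontal lobe
29,frontal lobe
30,temporal lobe
31,temporal lobe
32,parietal lobe
33,parietal lobe
34,caudate nucleus
35,caudate nucleus
36,nucleus accumbens
37,nucleus accumbens
38,basal ganglia
39,basal ganglia
40,thalamus
41,thalamus
42,basal ganglia
43,basal ganglia
44,corpus callosum
45,lateral ventricles
46,lateral ventricles
47,lateral ventricles
48,lateral ventricles
49,third ventricle
50,precentral gyrus
51,precentral gyrus
52,orbitofrontal cortex
53,orbitofrontal cortex
54,orbitofrontal cortex
55,orbitofrontal cortex
56,frontal lobe
57,frontal lobe
58,frontal lobe
59,frontal lobe
60,parietal lobe
61,parietal lobe
62,parietal lobe
63,parietal lobe
64,occipital lobe
65,occipital lobe
66,occipital lobe
67,occipital lobe
68,orbitofrontal cortex
69,orbitofrontal cortex
70,frontal lobe
71,frontal lobe
72,frontal lobe
73,frontal lobe
74,substantia nigra
75,substantia nigra
76,subgenual and subcallosal cortex
77,subgenual and subcallosal cortex
78,subgenual and subcallosal cortex
79,subgenual and subcallosal cortex
80,subgenual and subcallosal cortex
81,subgenual and subcallosal cortex
82,temporal lobe
83,temporal lobe
84,deep white matter
85,deep white matter
86,deep white matter
87,deep white matter
88,deep white matter
89,deep white matter
90,deep white matter
91,deep white matter
92,deep white matter
93,deep white matter
94,deep white matter
95,deep white matter
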