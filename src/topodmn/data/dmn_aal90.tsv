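aal_index	abbreviation	hemisphere	name
13	IFGtriang.L	left	Inferior frontal gyrus pars triangularis
14	IFGtriang.R	right	Inferior frontal gyrus pars triangularis
23	SFGmed.L	left	Medial frontal gyrus
24	SFGmed.R	right	Medial frontal gyrus
25	ORBsupmed.L	left	Superior medial orbital frontal cortex
26	ORBsupmed.R	right	Superior medial orbital frontal cortex
31	ACG.L	left	Anterior cingulate and paracingulate gyrus
32	ACG.R	right	Anterior cingulate and paracingulate gyrus
35	PCG.L	left	Posterior cingulate gyrus
36	PCG.R	right	Posterior cingulate gyrus
39	PHG.L	left	Parahippocampal gyrus
40	PHG.R	right	Parahippocampal gyrus
45	CUN.L	left	Cuneus
46	CUN.R	right	Cuneus
63	SMG.L	left	Supramarginal gyrus
64	SMG.R	right	Supramarginal gyrus
65	ANG.L	left	Angular gyrus
66	ANG.R	right	Angular gyrus
67	PCUN.L	left	Precuneus
68	PCUN.R	right	Precuneus
81	STG.L	left	Superior temporal gyrus
82	STG.R	right	Superior temporal gyrus
83	TPOsup.L	left	Temporal pole: superior temporal gyrus
84	TPOsup.R	right	Temporal pole: superior temporal gyrus
85	MTG.L	left	Middle temporal gyrus
86	MTG.R	right	Middle temporal gyrus
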