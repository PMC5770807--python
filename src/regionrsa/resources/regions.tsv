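name	alias	hemisphere	mni_x	mni_y	mni_z
Frontal pole	FPole	left	-25	61	-5
Frontal pole	FPole	right	25	61	-5
Superior frontal	SF	left	-18	30	44
Superior frontal	SF	right	18	30	44
Middle frontal	MF	left	-39	40	27
Middle frontal	MF	right	39	40	27
Inferior frontal	IF	left	-50	20	11
Inferior frontal	IF	right	50	20	11
Orbital frontal	OF	left	-23	28	-16
Orbital frontal	OF	right	23	28	-16
Ventral premotor	VPM	left	-40	2	34
Ventral premotor	VPM	right	40	2	34
Dorsal lateral premotor	DLPM	left	-35	-10	57
Dorsal lateral premotor	DLPM	right	35	-10	57
Insula	Insula	left	-40	6	1
Insula	Insula	right	40	6	1
Cingular anterior	CingA	left	-3	31	23
Cingular anterior	CingA	right	3	31	23
Cingular posterior	CingP	left	-2	-26	46
Cingular posterior	CingP	right	2	-26	46
Postcentral gyrus	Postcen	left	-43	-32	49
Postcentral gyrus	Postcen	right	43	-32	49
Central sulcus	Central	left	-41	-16	51
Central sulcus	Central	right	41	-16	51
Temporal pole	TPole	left	-32	12	-38
Temporal pole	TPole	right	32	12	-38
Superior temporal gyrus anterior	STGa	left	-52	8	-10
Superior temporal gyrus anterior	STGa	right	52	8	-10
Superior temporal gyrus posterior	STGp	left	-55	-29	16
Superior temporal gyrus posterior	STGp	right	55	-29	16
Middle temporal anterior	MTa	left	-65	-14	-20
Middle temporal anterior	MTa	right	65	-14	-20
Middle temporal posterior	MTp	left	-67	-50	-2
Middle temporal posterior	MTp	right	67	-50	-2
Superior temporal sulcus anterior	STSa	left	-52	-24	-6
Superior temporal sulcus anterior	STSa	right	52	-24	-6
Superior temporal sulcus posterior	STSp	left	-51	-61	17
Superior temporal sulcus posterior	STSp	right	51	-61	17
Inferior temporal anterior	ITa	left	-58	-15	-28
Inferior temporal anterior	ITa	right	58	-15	-28
Inferior temporal posterior	ITp	left	-50	-56	-20
Inferior temporal posterior	ITp	right	50	-56	-20
Parahippocampal gyrus	PhG	left	-18	-20	-22
Parahippocampal gyrus	PhG	right	18	-20	-22
Fusiform gyrus	FG	left	-37	-58	-19
Fusiform gyrus	FG	right	37	-58	-19
Medial occipito-temporal	MedOT	left	-26	-53	-11
Medial occipito-temporal	MedOT	right	26	-53	-11
Collateral sulcus anterior	ColSa	left	-41	-25	-26
Collateral sulcus anterior	ColSa	right	41	-25	-26
Precuneus	Precun	left	-6	-66	47
Precuneus	Precun	right	6	-66	47
Angular gyrus	AngG	left	-49	-59	40
Angular gyrus	AngG	right	49	-59	40
Inferior parietal gyrus	IP	left	-57	-35	31
Inferior parietal gyrus	IP	right	57	-35	31
Superior parietal gyrus	SP	left	-21	-65	59
Superior parietal gyrus	SP	right	21	-65	59
Intraparietal sulcus	IPS	left	-30	-60	43
Intraparietal sulcus	IPS	right	30	-60	43
Parieto-occipital sulcus	POS	left	-14	-69	24
Parieto-occipital sulcus	POS	right	14	-69	24
Lunate sulcus	LunS	left	-30	-90	9
Lunate sulcus	LunS	right	30	-90	9
Cuneus	Cuneus	left	-3	-83	21
Cuneus	Cuneus	right	3	-83	21
Superior occipital sulcus	SOS	left	-27	-84	25
Superior occipital sulcus	SOS	right	27	-84	25
Superior occipital gyrus	SOG	left	-16	-93	34
Superior occipital gyrus	SOG	right	16	-93	34
Occipital sulcus anterior	OSa	left	-44	-73	-1
Occipital sulcus anterior	OSa	right	44	-73	-1
Inferior occipital G and S	IO	left	-36	-90	-10
Inferior occipital G and S	IO	right	36	-90	-10
Middle occipital gyrus	MO	left	-39	-84	19
Middle occipital gyrus	MO	right	39	-84	19
Lingual gyrus	LingG	left	-8	-67	0
Lingual gyrus	LingG	right	8	-67	0
Calcarine sulcus	Calcarine	left	-17	-70	7
Calcarine sulcus	Calcarine	right	17	-70	7
Occipital pole	OPole	left	-15	-101	-4
Occipital pole	OPole	right	15	-101	-4
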