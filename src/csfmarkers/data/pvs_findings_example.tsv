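metric	lobe	mask	term	beta	se	t	p_perm
DM	frontal	L-parsopercularis	Group⋅Age	0.0066	0.0030	2.21	0.029
DM	frontal	L-caudalmiddlefrontal	Age	0.0041	0.0016	2.62	0.010
VF	frontal	L-caudalmiddlefrontal	Age	0.0001	0.0001	2.48	0.017
VF	frontal	L-parsopercularis	Age	0.0002	0.0001	3.01	0.002
DM	frontal	L-parstriangularis	Age	0.0041	0.0015	2.74	0.009
VF	frontal	L-precentral	Age	0.0001	0.0000	2.30	0.025
DM	frontal	L-rostralmiddlefrontal	Age	0.0039	0.0012	3.15	0.003
VF	frontal	L-superiorfrontal	Age	0.0001	0.0001	1.96	0.047
DM	frontal	R-parsopercularis	Age	0.0045	0.0020	2.22	0.029
VF	frontal	R-parsopercularis	Age	0.0001	0.0001	2.45	0.015
CF	frontal	R-parstriangularis	Age	0.0000	0.0000	2.64	0.011
DM	frontal	R-parstriangularis	Age	0.0054	0.0018	2.98	0.005
VF	frontal	R-parstriangularis	Age	0.0002	0.0000	3.75	0.000
VF	frontal	R-precentral	Age	0.0001	0.0000	2.08	0.039
DM	frontal	R-rostralmiddlefrontal	Age	0.0030	0.0010	2.97	0.004
VF	frontal	R-superiorfrontal	Age	0.0001	0.0000	2.27	0.026
CF	parietal	R-inferiorparietal	Group	0.0002	0.0001	1.98	0.048
CF	parietal	R-supramarginal	Group	0.0003	0.0001	2.41	0.019
CF	parietal	L-inferiorparietal	Group⋅Age	0.0000	0.0000	2.68	0.010
DM	parietal	L-inferiorparietal	Group⋅Age	0.0069	0.0032	2.19	0.032
VF	parietal	L-inferiorparietal	Group⋅Age	0.0003	0.0001	3.14	0.002
DM	parietal	L-precuneus	Group⋅Age	0.0061	0.0023	2.68	0.008
VF	parietal	L-precuneus	Group⋅Age	0.0001	0.0001	2.07	0.046
CF	parietal	L-precuneus	Age	0.0000	0.0000	-2.01	0.045
DM	parietal	L-supramarginal	Age	0.0040	0.0018	2.19	0.028
DM	parietal	R-inferiorparietal	Age	0.0048	0.0020	2.37	0.023
VF	parietal	R-postcentral	Age	0.0001	0.0000	2.28	0.026
DM	parietal	R-precuneus	Age	0.0029	0.0015	1.96	0.048
VF	parietal	R-supramarginal	Age	0.0001	0.0000	2.46	0.019
CF	temporal	L-entorhinal	Group	-0.0004	0.0002	-2.13	0.037
DM	temporal	L-parahippocampal	Group	-0.4256	0.1644	-2.59	0.011
CF	temporal	R-transversetemporal	Group	0.0009	0.0004	2.48	0.014
VF	temporal	R-transversetemporal	Group	0.0034	0.0015	2.32	0.021
DM	temporal	L-fusiform	Group⋅Age	0.0050	0.0024	2.11	0.038
VF	temporal	L-inferiortemporal	Group⋅Age	0.0001	0.0001	2.39	0.021
DM	temporal	L-inferiortemporal	Age	0.0027	0.0012	2.27	0.024
CF	temporal	L-middletemporal	Age	0.0000	0.0000	2.07	0.041
VF	temporal	L-middletemporal	Age	0.0001	0.0000	2.23	0.028
VF	temporal	R-inferiortemporal	Age	0.0001	0.0000	2.06	0.040
VF	temporal	R-middletemporal	Age	0.0001	0.0000	2.36	0.021
DM	occipital	L-lingual	Group	-0.3454	0.1623	-2.13	0.036
VF	occipital	L-pericalcarine	Group	-0.0016	0.0008	-1.98	0.048
DM	occipital	L-lingual	Age	-0.0198	0.0093	-2.13	0.037
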