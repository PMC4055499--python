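region	v1	v2	p	pct_change
frontal_left_anterior_cingulum	2.908	3.031	0.0008	4.230
frontal_left_mid_anterior_cingulum	2.875	2.985	0.0004	3.826
frontal_left_transverse_pole	2.982	3.119	0.0083	4.594
occipital_left_middle	2.795	2.939	0.0002	5.152
occipital_left_superior	2.341	2.453	0.0056	4.784
occipital_left_lingual	2.215	2.308	0.0089	4.199
occipital_left_middle_lunatus	2.118	2.220	0.0026	4.816
occipital_right_lingual	2.287	2.383	0.0031	4.198
occipital_right_calcarine	2.129	2.231	0.0023	4.791
parietal_left_inferior_angular	3.036	3.166	0.0016	4.282
parietal_left_inferior_supramar	2.987	3.107	0.0004	4.017
parietal_left_rectus	2.807	2.903	0.0089	3.420
parietal_left_post_lateral_fissure	2.616	2.718	0.0018	3.900
parietal_left_occipital_junction	2.428	2.531	0.0060	4.242
parietal_left_postcentral	2.338	2.444	0.0036	4.534
parietal_right_postcentral	2.311	2.423	0.0029	4.846
temporal_left_superior	2.691	2.792	0.0009	3.753
temporal_right_superior	2.731	2.806	0.0089	2.746
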