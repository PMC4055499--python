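region	v1	v2	p	pct_change
frontal_gm_left_inferior	0.852	0.938	0.0068	10.094
frontal_gm_left_superior	18.97	20.05	0.0010	5.693
frontal_gm_right_superior	18.18	19.12	0.0034	5.171
frontal_gm_right_medial_orbital_olfactory	1.204	1.104	0.0034	-8.306
frontal_wm_left_lateral_orbitofrontal	5.761	5.562	0.0090	-3.454
occipital_gm_left_middle	4.941	5.292	0.0056	7.104
occipital_gm_left_superior	2.623	2.902	0.0002	10.637
occipital_gm_right_superior	3.279	3.582	0.0017	9.241
parietal_gm_left_postcentral	3.961	4.230	0.0064	6.791
parietal_gm_right_superior	5.482	5.888	0.0054	7.406
parietal_gm_right_postcentral	3.996	4.319	0.0020	8.083
parietal_gm_right_precuneus	6.495	7.031	0.0006	8.253
parietal_wm_left_postcentral	5.771	5.483	0.0074	-4.990
parietal_wm_right_supramarginal	7.791	7.410	0.0054	-4.890
temporal_wm_left_fusiform	5.811	5.567	0.0085	-4.199
temporal_wm_right_inferior	5.157	4.890	0.0023	-5.177
temporal_wm_right_superior	5.779	5.543	0.0058	-4.084
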