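structure_id	group	chain_energy_kcal_mol	residue_energy_kcal_mol
ATTR_synth_1	ATTR	-70.2	-0.724
ATTR_synth_2	ATTR	-67.8	-0.699
ATTR_synth_3	ATTR	-65.1	-0.700
ATTR_synth_4	ATTR	-62.4	-0.657
ATTR_synth_5	ATTR	-60.0	-0.600
ATTR_synth_6	ATTR	-57.6	-0.565
ATTR_synth_7	ATTR	-55.4	-0.565
atlas_synth_001	other	-24.1	-0.177
atlas_synth_002	other	-19.3	-0.190
atlas_synth_003	other	-29.4	-0.213
atlas_synth_004	other	-26.6	-0.215
atlas_synth_005	other	-33.9	-0.556
atlas_synth_006	other	-34.9	-0.332
atlas_synth_007	other	-4.0	-0.038
atlas_synth_008	other	-41.0	-0.383
atlas_synth_009	other	-28.2	-0.513
atlas_synth_010	other	-4.0	-0.034
atlas_synth_011	other	-37.0	-0.561
atlas_synth_012	other	-42.1	-1.028
atlas_synth_013	other	-32.3	-0.521
atlas_synth_014	other	-43.1	-0.957
atlas_synth_015	other	-28.7	-0.346
atlas_synth_016	other	-39.3	-0.357
atlas_synth_017	other	-34.5	-0.305
atlas_synth_018	other	-4.5	-0.089
atlas_synth_019	other	-27.1	-0.215
atlas_synth_020	other	-19.1	-0.270
atlas_synth_021	other	-19.7	-0.159
atlas_synth_022	other	-40.7	-0.275
atlas_synth_023	other	-19.3	-0.138
atlas_synth_024	other	-29.4	-0.204
atlas_synth_025	other	-33.1	-0.447
atlas_synth_026	other	-23.3	-0.180
atlas_synth_027	other	-35.0	-0.547
atlas_synth_028	other	-37.9	-0.729
atlas_synth_029	other	-30.8	-0.560
atlas_synth_030	other	-22.5	-0.166
atlas_synth_031	other	-31.0	-0.240
atlas_synth_032	other	-18.2	-0.186
atlas_synth_033	other	-19.6	-0.272
atlas_synth_034	other	-7.0	-0.050
atlas_synth_035	other	-36.2	-0.272
atlas_synth_036	other	-37.4	-0.550
atlas_synth_037	other	-15.9	-0.218
atlas_synth_038	other	-35.6	-0.246
atlas_synth_039	other	-6.3	-0.086
atlas_synth_040	other	-15.1	-0.140
atlas_synth_041	other	-10.1	-0.081
atlas_synth_042	other	-14.1	-0.191
atlas_synth_043	other	-26.9	-0.413
atlas_synth_044	other	-20.5	-0.183
atlas_synth_045	other	-4.0	-0.054
atlas_synth_046	other	-4.0	-0.078
atlas_synth_047	other	-62.0	-0.602
atlas_synth_048	other	-50.6	-0.562
atlas_synth_049	other	-50.0	-0.758
atlas_synth_050	other	-24.6	-0.222
atlas_synth_051	other	-12.2	-0.133
atlas_synth_052	other	-48.3	-0.338
atlas_synth_053	other	-4.0	-0.055
atlas_synth_054	other	-43.6	-0.969
atlas_synth_055	other	-30.4	-0.330
atlas_synth_056	other	-4.0	-0.027
atlas_synth_057	other	-32.7	-0.268
atlas_synth_058	other	-59.2	-0.529
atlas_synth_059	other	-32.1	-0.365
atlas_synth_060	other	-30.3	-0.606
atlas_synth_061	other	-25.3	-0.180
atlas_synth_062	other	-43.6	-0.597
atlas_synth_063	other	-21.4	-0.153
atlas_synth_064	other	-27.6	-0.266
atlas_synth_065	other	-9.8	-0.102
atlas_synth_066	other	-41.7	-0.673
atlas_synth_067	other	-23.4	-0.167
atlas_synth_068	other	-39.7	-0.355
atlas_synth_069	other	-30.6	-0.212
atlas_synth_070	other	-33.6	-0.448
atlas_synth_071	other	-27.6	-0.468
atlas_synth_072	other	-25.7	-0.279
atlas_synth_073	other	-20.0	-0.202
atlas_synth_074	other	-35.9	-0.348
atlas_synth_075	other	-21.4	-0.225
atlas_synth_076	other	-32.3	-0.567
atlas_synth_077	other	-20.0	-0.180
atlas_synth_078	other	-19.6	-0.148
atlas_synth_079	other	-44.6	-0.506
atlas_synth_080	other	-36.6	-0.324
atlas_synth_081	other	-15.9	-0.222
atlas_synth_082	other	-49.7	-0.469
atlas_synth_083	other	-37.8	-0.353
atlas_synth_084	other	-31.7	-0.233
atlas_synth_085	other	-41.7	-0.772
atlas_synth_086	other	-26.2	-0.212
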