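BCELL_MODULE_SYNTHETIC	synthetic placeholder for the 71-gene B-cell module	SYNBCELL_001	SYNBCELL_002	SYNBCELL_003	SYNBCELL_004	SYNBCELL_005	SYNBCELL_006	SYNBCELL_007	SYNBCELL_008	SYNBCELL_009	SYNBCELL_010	SYNBCELL_011	SYNBCELL_012	SYNBCELL_013	SYNBCELL_014	SYNBCELL_015	SYNBCELL_016	SYNBCELL_017	SYNBCELL_018	SYNBCELL_019	SYNBCELL_020	SYNBCELL_021	SYNBCELL_022	SYNBCELL_023	SYNBCELL_024	SYNBCELL_025	SYNBCELL_026	SYNBCELL_027	SYNBCELL_028	SYNBCELL_029	SYNBCELL_030	SYNBCELL_031	SYNBCELL_032	SYNBCELL_033	SYNBCELL_034	SYNBCELL_035	SYNBCELL_036	SYNBCELL_037	SYNBCELL_038	SYNBCELL_039	SYNBCELL_040	SYNBCELL_041	SYNBCELL_042	SYNBCELL_043	SYNBCELL_044	SYNBCELL_045	SYNBCELL_046	SYNBCELL_047	SYNBCELL_048	SYNBCELL_049	SYNBCELL_050	SYNBCELL_051	SYNBCELL_052	SYNBCELL_053	SYNBCELL_054	SYNBCELL_055	SYNBCELL_056	SYNBCELL_057	SYNBCELL_058	SYNBCELL_059	SYNBCELL_060	SYNBCELL_061	SYNBCELL_062	SYNBCELL_063	SYNBCELL_064	SYNBCELL_065	SYNBCELL_066	SYNBCELL_067	SYNBCELL_068	SYNBCELL_069	SYNBCELL_070	SYNBCELL_071
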