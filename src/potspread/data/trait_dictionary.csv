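trait_id,block,in_analysis
dec_001,decoration,True
dec_002,decoration,True
dec_003,decoration,True
dec_004,decoration,True
dec_005,decoration,True
dec_006,decoration,True
dec_007,decoration,True
dec_008,decoration,True
dec_009,decoration,True
dec_010,decoration,True
dec_011,decoration,True
dec_012,decoration,True
dec_013,decoration,True
dec_014,decoration,True
dec_015,decoration,True
dec_016,decoration,True
dec_017,decoration,True
dec_018,decoration,True
dec_019,decoration,True
dec_020,decoration,True
dec_021,decoration,True
dec_022,decoration,True
dec_023,decoration,True
dec_024,decoration,True
dec_025,decoration,True
dec_026,decoration,True
dec_027,decoration,True
dec_028,decoration,True
dec_029,decoration,True
dec_030,decoration,True
dec_031,decoration,True
dec_032,decoration,True
dec_033,decoration,True
dec_034,decoration,True
dec_035,decoration,True
dec_036,decoration,True
dec_037,decoration,True
dec_038,decoration,True
dec_039,decoration,True
dec_040,decoration,True
dec_041,decoration,True
dec_042,decoration,True
dec_043,decoration,True
dec_044,decoration,True
dec_045,decoration,False
dec_046,decoration,False
dec_047,decoration,False
dec_048,decoration,False
dec_049,decoration,False
dec_050,decoration,False
dec_051,decoration,False
dec_052,decoration,False
dec_053,decoration,False
dec_054,decoration,False
dec_055,decoration,False
dec_056,decoration,False
dec_057,decoration,False
dec_058,decoration,False
dec_059,decoration,False
dec_060,decoration,False
dec_061,decoration,False
mor_001,morphology,True
mor_002,morphology,True
mor_003,morphology,True
mor_004,morphology,True
mor_005,morphology,True
mor_006,morphology,True
mor_007,morphology,True
mor_008,morphology,True
mor_009,morphology,True
mor_010,morphology,True
mor_011,morphology,True
mor_012,morphology,True
mor_013,morphology,True
mor_014,morphology,True
mor_015,morphology,True
mor_016,morphology,True
mor_017,morphology,True
mor_018,morphology,True
mor_019,morphology,True
mor_020,morphology,True
mor_021,morphology,True
mor_022,morphology,True
mor_023,morphology,True
mor_024,morphology,True
mor_025,morphology,True
mor_026,morphology,True
mor_027,morphology,True
mor_028,morphology,True
mor_029,morphology,True
mor_030,morphology,True
mor_031,morphology,True
mor_032,morphology,True
mor_033,morphology,True
mor_034,morphology,True
mor_035,morphology,True
mor_036,morphology,True
mor_037,morphology,True
mor_038,morphology,True
mor_039,morphology,True
mor_040,morphology,True
mor_041,morphology,True
mor_042,morphology,True
mor_043,morphology,True
mor_044,morphology,True
mor_045,morphology,True
mor_046,morphology,False
mor_047,morphology,False
mor_048,morphology,False
mor_049,morphology,False
mor_050,morphology,False
mor_051,morphology,False
mor_052,morphology,False
mor_053,morphology,False
mor_054,morphology,False
mor_055,morphology,False
mor_056,morphology,False
mor_057,morphology,False
mor_058,morphology,False
mor_059,morphology,False
mor_060,morphology,False
mor_061,morphology,False
tec_001,technology,True
tec_002,technology,True
tec_003,technology,True
tec_004,technology,True
tec_005,technology,True
tec_006,technology,True
tec_007,technology,True
tec_008,technology,True
tec_009,technology,True
tec_010,technology,True
tec_011,technology,True
tec_012,technology,True
tec_013,technology,True
tec_014,technology,True
tec_015,technology,True
tec_016,technology,True
tec_017,technology,True
tec_018,technology,True
tec_019,technology,True
tec_020,technology,True
tec_021,technology,True
tec_022,technology,True
tec_023,technology,True
tec_024,technology,True
tec_025,technology,True
tec_026,technology,True
tec_027,technology,True
tec_028,technology,True
tec_029,technology,True
tec_030,technology,True
tec_031,technology,True
tec_032,technology,True
tec_033,technology,True
tec_034,technology,True
tec_035,technology,True
tec_036,technology,True
tec_037,technology,True
tec_038,technology,True
tec_039,technology,True
tec_040,technology,True
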