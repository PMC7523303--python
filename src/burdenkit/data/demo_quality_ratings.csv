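entity_id,entity_kind,source,contribution,data_rating,methods_rating
disease_001,disease,primary,1,A,A
disease_002,disease,primary,1,A,A
disease_003,disease,primary,1,A,A
disease_004,disease,primary,1,A,A
disease_005,disease,primary,1,A,A
disease_006,disease,primary,1,A,A
disease_007,disease,primary,1,A,A
disease_008,disease,primary,1,A,A
disease_009,disease,primary,1,A,A
disease_010,disease,primary,1,A,A
disease_011,disease,primary,1,A,A
disease_012,disease,primary,1,A,A
disease_013,disease,primary,1,A,A
disease_014,disease,primary,1,A,A
disease_015,disease,primary,1,A,A
disease_016,disease,primary,1,A,A
disease_017,disease,primary,1,A,A
disease_018,disease,primary,1,A,A
disease_019,disease,primary,1,A,A
disease_020,disease,primary,1,A,A
disease_021,disease,primary,1,A,A
disease_022,disease,primary,1,A,A
disease_023,disease,primary,1,A,A
disease_024,disease,primary,1,A,A
disease_025,disease,primary,1,A,A
disease_026,disease,primary,1,A,A
disease_027,disease,primary,1,A,A
disease_028,disease,primary,1,A,A
disease_029,disease,primary,1,A,A
disease_030,disease,primary,1,A,A
disease_031,disease,primary,1,A,A
disease_032,disease,primary,1,A,A
disease_033,disease,primary,1,A,A
disease_034,disease,primary,1,A,A
disease_035,disease,primary,1,A,A
disease_036,disease,primary,1,A,A
disease_037,disease,primary,1,A,A
disease_038,disease,primary,1,A,A
disease_039,disease,primary,1,A,A
disease_040,disease,primary,1,A,A
disease_041,disease,primary,1,A,A
disease_042,disease,primary,1,A,A
disease_043,disease,primary,1,A,A
disease_044,disease,primary,1,A,A
disease_045,disease,primary,1,A,A
disease_046,disease,primary,1,A,A
disease_047,disease,primary,1,A,A
disease_048,disease,primary,1,A,A
disease_049,disease,primary,1,A,A
disease_050,disease,primary,1,A,A
disease_051,disease,primary,1,A,A
disease_052,disease,primary,1,A,A
disease_053,disease,primary,1,A,A
disease_054,disease,primary,1,A,A
disease_055,disease,primary,1,A,A
disease_056,disease,primary,1,A,A
disease_057,disease,primary,1,A,B
disease_058,disease,primary,1,A,B
disease_059,disease,primary,1,A,B
disease_060,disease,primary,1,A,B
disease_061,disease,primary,1,A,B
disease_062,disease,primary,1,A,B
disease_063,disease,primary,1,A,B
disease_064,disease,primary,1,A,B
disease_065,disease,primary,1,A,B
disease_066,disease,primary,1,A,B
disease_067,disease,primary,1,A,B
disease_068,disease,primary,1,A,B
disease_069,disease,primary,1,A,B
disease_070,disease,primary,1,A,B
disease_071,disease,primary,1,A,B
disease_072,disease,primary,1,A,B
disease_073,disease,primary,1,A,B
disease_074,disease,primary,1,B,B
disease_075,disease,primary,1,B,B
disease_076,disease,primary,1,B,B
disease_077,disease,primary,1,B,B
disease_078,disease,primary,1,B,B
disease_079,disease,primary,1,B,B
disease_080,disease,primary,1,B,B
disease_081,disease,primary,1,B,B
disease_082,disease,primary,1,B,B
disease_083,disease,primary,1,B,B
disease_084,disease,primary,1,B,B
disease_085,disease,primary,1,B,B
disease_086,disease,primary,1,B,B
disease_087,disease,primary,1,B,B
disease_088,disease,primary,1,B,B
disease_089,disease,primary,1,B,B
disease_090,disease,primary,1,B,B
disease_091,disease,primary,1,B,B
disease_092,disease,primary,1,B,B
disease_093,disease,primary,1,B,B
disease_094,disease,primary,1,B,B
disease_095,disease,primary,1,B,C
disease_096,disease,primary,1,B,C
disease_097,disease,primary,1,B,C
disease_098,disease,primary,1,B,C
disease_099,disease,primary,1,B,C
disease_100,disease,primary,1,B,C
disease_101,disease,primary,1,B,C
disease_102,disease,primary,1,B,C
disease_103,disease,primary,1,B,C
disease_104,disease,primary,1,B,C
disease_105,disease,primary,1,B,C
disease_106,disease,primary,1,B,C
disease_107,disease,primary,1,B,C
disease_108,disease,primary,1,B,C
disease_109,disease,primary,1,B,C
disease_110,disease,primary,1,B,C
disease_111,disease,primary,1,B,C
disease_112,disease,primary,1,B,C
disease_113,disease,primary,1,B,C
disease_114,disease,primary,1,B,C
disease_115,disease,primary,1,B,C
disease_116,disease,primary,1,B,C
disease_117,disease,primary,1,B,C
disease_118,disease,primary,1,B,C
disease_119,disease,primary,1,C,C
disease_120,disease,primary,1,C,C
disease_121,disease,primary,1,C,C
disease_122,disease,primary,1,C,C
disease_123,disease,primary,1,C,C
disease_124,disease,primary,1,C,C
disease_125,disease,primary,1,C,C
disease_126,disease,primary,1,C,C
disease_127,disease,primary,1,C,C
disease_128,disease,primary,1,C,C
disease_129,disease,primary,1,C,C
disease_130,disease,primary,1,C,C
disease_131,disease,primary,1,C,C
disease_132,disease,primary,1,C,C
disease_133,disease,primary,1,C,C
disease_134,disease,primary,1,C,C
disease_135,disease,primary,1,C,C
disease_136,disease,primary,1,C,C
disease_137,disease,primary,1,C,C
disease_138,disease,primary,1,C,C
disease_139,disease,primary,1,C,C
disease_140,disease,primary,1,C,C
disease_141,disease,primary,1,C,C
disease_142,disease,primary,1,C,C
disease_143,disease,primary,1,C,C
disease_144,disease,primary,1,C,C
disease_145,disease,primary,1,C,C
disease_146,disease,primary,1,C,C
disease_147,disease,primary,1,C,C
disease_148,disease,primary,1,C,C
disease_149,disease,primary,1,C,C
disease_150,disease,primary,1,C,C
disease_151,disease,primary,1,C,C
disease_152,disease,primary,1,C,C
disease_153,disease,primary,1,C,C
disease_154,disease,primary,1,C,C
disease_155,disease,primary,1,C,C
disease_156,disease,primary,1,C,D
disease_157,disease,primary,1,C,D
disease_158,disease,primary,1,C,D
disease_159,disease,primary,1,C,D
disease_160,disease,primary,1,C,D
disease_161,disease,primary,1,C,D
disease_162,disease,primary,1,C,D
disease_163,disease,primary,1,C,D
disease_164,disease,primary,1,D,D
disease_165,disease,primary,1,D,D
disease_166,disease,primary,1,D,D
disease_167,disease,primary,1,D,D
disease_168,disease,primary,1,D,D
disease_169,disease,primary,1,D,D
disease_170,disease,primary,1,D,D
disease_171,disease,primary,1,D,D
disease_172,disease,primary,1,D,D
disease_173,disease,primary,1,D,D
disease_174,disease,primary,1,D,D
disease_175,disease,primary,1,D,D
disease_176,disease,primary,1,D,D
disease_177,disease,primary,1,D,D
disease_178,disease,primary,1,D,D
disease_179,disease,primary,1,D,D
disease_180,disease,primary,1,D,D
disease_181,disease,primary,1,D,D
disease_182,disease,primary,1,D,D
disease_183,disease,primary,1,D,D
disease_184,disease,primary,1,D,D
disease_185,disease,primary,1,D,D
disease_186,disease,primary,1,D,D
disease_187,disease,primary,1,D,D
disease_188,disease,primary,1,D,D
disease_189,disease,primary,1,D,D
disease_190,disease,primary,1,D,D
disease_191,disease,primary,1,D,E
disease_192,disease,primary,1,D,E
disease_193,disease,primary,1,E,E
disease_194,disease,primary,1,E,E
risk_001,risk_factor,primary,1,A,A
risk_002,risk_factor,primary,1,A,A
risk_003,risk_factor,primary,1,A,B
risk_004,risk_factor,primary,1,B,B
risk_005,risk_factor,primary,1,B,B
risk_006,risk_factor,primary,1,B,B
risk_007,risk_factor,primary,1,B,B
risk_008,risk_factor,primary,1,B,B
risk_009,risk_factor,primary,1,B,B
risk_010,risk_factor,primary,1,B,C
risk_011,risk_factor,primary,1,B,C
risk_012,risk_factor,primary,1,B,C
risk_013,risk_factor,primary,1,B,C
risk_014,risk_factor,primary,1,C,C
risk_015,risk_factor,primary,1,C,C
risk_016,risk_factor,primary,1,C,D
risk_017,risk_factor,primary,1,D,
risk_018,risk_factor,primary,1,E,
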