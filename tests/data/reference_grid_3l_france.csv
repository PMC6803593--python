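model_id,me,mae,rmse,mae_rank,rmse_rank,final_rank
OLS 1,-0.0001,0.1856,0.2437,24,22,22
OLS 2,0.0005,0.1794,0.2408,18,12,14
OLS 3,0.0000,0.1807,0.2435,21,21,21
OLS 4,-0.0002,0.1835,0.2441,23,23,23
OLS 5,0.0012,0.1807,0.2433,20,20,20
OLS 6,0.0000,0.1786,0.2391,17,7,13
BETA 1,0.1051,0.2067,0.2771,29,29,29
BETA 2,0.0904,0.2009,0.2716,26,26,26
BETA 3,0.0884,0.2028,0.2745,27,28,28
BETA 4,0.1040,0.2102,0.2825,30,30,30
BETA 5,0.0758,0.2040,0.2728,28,27,27
BETA 6,0.0579,0.1915,0.2645,25,25,25
ALD 1-1,0.0109,0.1765,0.2385,10,5,7
ALD 1-2,-0.0003,0.1739,0.2393,5,8,5
ALD 2-1,0.0088,0.1774,0.2393,11,9,10
ALD 2-2,-0.0006,0.1780,0.2422,15,16,16
ALD 3-1,0.0083,0.1800,0.2424,19,17,19
ALD 3-2,0.0003,0.1812,0.2463,22,24,24
ALD 4-1,0.0103,0.1756,0.2397,7,10,8
ALD 4-2,0.0012,0.1732,0.2401,3,11,6
ALD 5-1,0.0094,0.1783,0.2418,16,15,15
ALD 5-2,0.0005,0.1775,0.2431,12,19,18
ALD 6-1,0.0072,0.1778,0.2389,14,6,9
ALD 6-2,0.0031,0.1730,0.2328,1,1,1
OPM 1,0.0136,0.1744,0.2382,6,4,4
OPM 2,0.0119,0.1762,0.2415,9,14,12
OPM 3,0.0107,0.1776,0.2427,13,18,17
OPM 4,0.0093,0.1731,0.2339,2,2,2
OPM 5,0.0054,0.1759,0.2412,8,13,11
OPM 6,0.0076,0.1735,0.2381,4,3,3
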