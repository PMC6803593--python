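model_id,me,mae,rmse,mae_rank,rmse_rank,final_rank
OLS 1,0.0019,0.2672,0.3503,18,11,14
OLS 2,0.0019,0.2575,0.3475,8,5,6
OLS 3,0.0012,0.2558,0.3482,5,6,4
OLS 4,0.0028,0.2716,0.3511,21,12,16
OLS 5,0.0016,0.2592,0.3484,13,7,10
OLS 6,0.0185,0.2793,0.3923,26,27,27
BETA 1,0.0548,0.2714,0.3520,20,14,18
BETA 2,0.0544,0.2747,0.3584,24,18,21
BETA 3,0.0541,0.2751,0.3651,25,21,24
BETA 4,0.0552,0.2667,0.3537,17,16,17
BETA 5,0.0466,0.2728,0.3738,23,22,23
BETA 6,0.0568,0.2840,0.4081,28,28,28
ALD 1-1,0.0231,0.2575,0.3421,9,2,3
ALD 1-2,0.0091,0.2564,0.3487,7,8,9
ALD 1-3,0.0075,0.2575,0.3522,10,15,13
ALD 2-1,0.0210,0.2583,0.3459,12,3,8
ALD 2-2,0.0003,0.2552,0.3549,4,17,11
ALD 2-3,-0.0091,0.2712,0.3749,19,23,22
ALD 3-1,0.0209,0.2601,0.3499,14,9,12
ALD 3-2,0.0018,0.2578,0.3620,11,19,15
ALD 4-1,0.0255,0.2558,0.3416,6,1,1
ALD 4-2,0.0034,0.2486,0.3514,1,13,7
ALD 4-3,0.0151,0.2661,0.3790,16,24,20
ALD 5-1,0.0222,0.2540,0.3462,3,4,2
ALD 5-2,0.0105,0.2497,0.3503,2,10,5
ALD 5-3,0.0059,0.2632,0.3643,15,20,19
ALD 6-1,0.0375,0.2721,0.3848,22,25,25
ALD 6-2,0.0094,0.2798,0.3895,27,26,26
OPM 1,0.3637,0.4399,0.4870,31,30,31
OPM 2,0.3661,0.4444,0.4941,32,32,32
OPM 3,0.3670,0.4483,0.4990,33,33,33
OPM 4,0.3642,0.4356,0.4862,30,29,29
OPM 5,0.3664,0.4356,0.4911,29,31,30
OPM 6,0.3837,0.4576,0.5214,34,34,34
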