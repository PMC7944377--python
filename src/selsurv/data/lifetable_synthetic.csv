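band_start,sex,s5
50,man,0.937426
50,woman,0.941949
55,man,0.906837
55,woman,0.914109
60,man,0.862431
60,woman,0.873839
65,man,0.799328
65,woman,0.816674
70,man,0.712499
70,woman,0.737777
75,man,0.598691
75,woman,0.633383
80,man,0.460064
80,woman,0.503695
85,man,0.308822
85,woman,0.357068
90,man,0.168936
90,woman,0.212999
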