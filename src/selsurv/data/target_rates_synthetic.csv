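band_start,rate_per_1000py
65,2.0
70,4.5
75,10.0
80,22.0
85,40.0
90,80.0
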