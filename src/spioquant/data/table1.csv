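image,total_px,red_px,printed_pct,printed_est
1,3654,548,15,93
2,3782,529,14,88
3,4140,589,14.23,98
4,2950,502,17,84
5,3016,431,14.32,72
6,3762,412,11,70
7,2860,496,17.34,86
8,2700,324,12,40
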