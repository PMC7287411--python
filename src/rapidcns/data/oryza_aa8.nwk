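((((((SAT:0.002022,RUF:0.003527):0.000373,NIV:0.002659):0.001616,(BAR:0.001242,GLA:0.001793):0.001899):0.001268,GLU:0.004631):0.007018,LON:0.011113):0.003953,MER:0.014768);
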