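risk,confirmed,excluded,unknown,suspected
Low,0,0,7,0
Medium,0,0,0,0
High,0,0,0,0
No risk,0,0,0,0
No data,0,0,4,0
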