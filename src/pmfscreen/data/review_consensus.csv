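risk,confirmed,excluded,unknown,suspected
Low,0,37,62,0
Medium,3,8,8,6
High,2,1,2,1
No risk,0,0,3,0
No data,0,0,5,1
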