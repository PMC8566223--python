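key,value
consensus_threshold_N,0.50
consensus_threshold_O,0.30
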