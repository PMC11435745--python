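pesticide,adi,body_weight
lufenuron,0.015,60
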