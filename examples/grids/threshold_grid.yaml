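threshold: [5.0, 10.0, 15.0, 20.0]
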