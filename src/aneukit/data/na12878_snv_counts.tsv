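category	count
hom	1306544
het	2081141
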