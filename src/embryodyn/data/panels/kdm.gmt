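kdm	histone lysine demethylases (H3K4/H3K9/H3K27)	KDM4A	KDM4B	KDM4C	KDM4D	KDM5A	KDM5B	KDM5C	KDM5D	KDM6A	KDM6B
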