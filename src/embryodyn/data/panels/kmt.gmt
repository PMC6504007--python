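kmt	histone lysine methyltransferases (H3K4/H3K9/H3K27)	KMT2A	KMT2C	KMT2E	SUV39H1	SUV39H2	SETDB1	SETDB2	PRDM2	EZH1	EZH2
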