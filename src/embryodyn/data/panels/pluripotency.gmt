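pluripotency	core pluripotency factors of the pre-implantation embryo	KLF17	MYC	NANOG	KLF4	MBD3	SOX2	BMP4	POU5F1
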