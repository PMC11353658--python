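name	ec_number	p1_residues	p1prime_residues
ficin	3.4.22.3	FYW
papain	3.4.22.2	KR	ACDEFGHIKLMNPQRSTWY
bromelain	3.4.22.32	KAYG
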