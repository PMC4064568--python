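psimod_id	prefix	includes_coordinate	phospho
MOD:00696	p	true	true
MOD:00440	PalmC	false	false
MOD:00068	MyrG	false	false
MOD:01148	Ub	true	false
MOD:00064	AcK	true	false
MOD:00084	Me2K	true	false
MOD:00085	Me3K	true	false
MOD:00414	MeR	true	false
MOD:00818	GerGerC	false	false
MOD:00115	FarnC	false	false
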