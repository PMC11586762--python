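cohort	variants
misc_icl	S6G+R162W+S176F
misc_hge	S6G+R162Q
misc_hge	R162Q+S176F
misc_hge	P299L+A475T
misc_hge	R354H+Y446C
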