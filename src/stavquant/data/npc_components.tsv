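component	gene_id	substructure	synonyms
NUP110		nuclear basket
NUP96		outer ring
NUP76		NUP76 complex
NUP158		NUP76 complex
NUP149		NUP76 complex (FG)
NUP140		NUP76 complex (FG)
NUP62		central channel (FG)
NUP64		central channel (FG)
NUP75		central channel (FG)
NUP98		central channel (FG)
NUP132		nuclear basket
NUP92		nuclear basket	MLP2
NUP181		inner ring
NUP144		inner ring
NUP225		inner ring
NUP65		inner ring
NUP89		outer ring
NUP41		outer ring
NUP82		outer ring
SEC13		outer ring	Sec13
MEX67		transport factor
NMD3	Tb927.7.970	transport factor
RanBP1	Tb927.11.3380	transport factor
RanBPL	Tb927.10.8650	transport factor
exportin 1	Tb927.11.14340	transport factor	XPO1|CRM1
GAP	Tb927.10.7680	transport factor	RanGAP
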