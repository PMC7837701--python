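# Canonical class-selective markers for retinal cell classes.
# columns: class <TAB> gene
PR	RHO
PR	ARR3
PR	RCVRN
HC	ONECUT1
HC	ONECUT2
HC	LHX1
BC	VSX2
BC	OTX2
BC	VSX1
AC	TFAP2A
AC	SLC32A1
AC	GAD2
RGC	RBPMS
RGC	THY1
RGC	POU4F2
MG	SLC1A3
MG	RLBP1
MG	GLUL
OL	OLIG2
OL	PLP1
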