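pair5p	pair3p	dG37
AU	AU	-0.93
AU	UA	-1.10
AU	CG	-2.24
AU	GC	-2.08
AU	GU	-0.60
AU	UG	-0.60
UA	AU	-1.33
UA	UA	-0.93
UA	CG	-2.35
UA	GC	-2.11
UA	GU	-0.60
UA	UG	-0.60
CG	AU	-2.11
CG	UA	-2.08
CG	CG	-3.26
CG	GC	-2.36
CG	GU	-0.60
CG	UG	-0.60
GC	AU	-2.35
GC	UA	-2.24
GC	CG	-3.42
GC	GC	-3.26
GC	GU	-0.60
GC	UG	-0.60
GU	AU	-0.60
GU	UA	-0.60
GU	CG	-0.60
GU	GC	-0.60
GU	GU	-0.60
GU	UG	-0.60
UG	AU	-0.60
UG	UA	-0.60
UG	CG	-0.60
UG	GC	-0.60
UG	GU	-0.60
UG	UG	-0.60
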