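# base-pair stacking energies, kcal/mol; step = 5'pair over 3'pair
pair5	pair3	kcal
AU	AU	-1.2
AU	UA	-1.2
AU	GC	-2.1
AU	CG	-2.1
AU	GU	-0.9
AU	UG	-0.9
UA	AU	-1.2
UA	UA	-1.2
UA	GC	-2.1
UA	CG	-2.1
UA	GU	-0.9
UA	UG	-0.9
GC	AU	-2.1
GC	UA	-2.1
GC	GC	-3.0
GC	CG	-3.0
GC	GU	-1.8
GC	UG	-1.8
CG	AU	-2.1
CG	UA	-2.1
CG	GC	-3.0
CG	CG	-3.0
CG	GU	-1.8
CG	UG	-1.8
GU	AU	-0.9
GU	UA	-0.9
GU	GC	-1.8
GU	CG	-1.8
GU	GU	-0.6
GU	UG	-0.6
UG	AU	-0.9
UG	UA	-0.9
UG	GC	-1.8
UG	CG	-1.8
UG	GU	-0.6
UG	UG	-0.6
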