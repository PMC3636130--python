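# RNA/RNA nearest-neighbor thermodynamic parameters, version 1.
# Watson-Crick stacks: Xia et al. 1998 (Biochemistry 37:14719);
# G.U wobble stacks: Mathews et al. 1999 (J Mol Biol 288:911) as revised in
# the Turner 2004 rules (Turner & Mathews 2010, NNDB); duplex initiation and
# per-terminal AU/GU penalty from the same series.
# dS derived from the published dH and dG37 via dS = (dH - dG37) / 310.15 K.
# Stack key convention: "XY/ZW" = top strand 5'-XY-3' over bottom strand
# 5'-ZW-3' (antiparallel: X pairs W, Y pairs Z); "XY/ZW" and "ZW/XY" name
# the same physical stack and one canonical row is stored per stack.
# dH in kcal/mol, dS in cal/(mol*K).
kind	key	dH	dS
stack	AA/UU	-6.8	-19.02
stack	AC/GU	-11.4	-29.66
stack	AG/CU	-10.5	-27.08
stack	AG/UU	-3.2	-8.38
stack	AU/AU	-9.4	-26.76
stack	AU/GU	-8.8	-23.86
stack	CA/UG	-10.4	-26.76
stack	CC/GG	-13.4	-32.56
stack	CG/CG	-10.6	-26.44
stack	CG/UG	-5.6	-13.54
stack	CU/GG	-12.1	-32.24
stack	GA/UC	-12.4	-32.24
stack	GA/UU	-12.8	-37.08
stack	GC/GC	-14.9	-37.08
stack	GC/GU	-12.6	-32.56
stack	GG/UC	-8.3	-21.92
stack	GG/UU	-13.5	-41.92
stack	GU/GU	-14.6	-51.27
stack	UA/UA	-7.7	-20.64
stack	UA/UG	-7.0	-19.35
stack	UG/UG	-9.3	-30.95
init	init	3.60	-1.61
terminal	terminal_AU_GU	3.70	10.32
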