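category	process	species	interactions
DISEASE	FOXM1 Signaling in Prostate Cancer	13	17
CELL_PROCESS	G2/M Phase Transition	47	65
CELL_PROCESS	Metaphase/Anaphase Phase Transition	15	22
CELL_PROCESS	Chromosome Condensation	22	36
PATHOLOGICAL	DREAM Complex and FOXM1/MYBL2 Promote Cell Cycle Progression in Cancer	36	56
CELL_PROCESS	Sister Chromatid Cohesion	27	41
CELL_PROCESS	Spindle Assembly	29	45
CELL_PROCESS	Kinetochore Assembly	49	73
CELL_PROCESS	Cell Cycle Overview	140	213
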