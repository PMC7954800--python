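strain	species	mode	gc_percent	busco_complete_pct
JBC27	Chromulinospumella sphaerica	heterotroph	51.3	21
A-R4-D6	Cornospumella fuschlensis	heterotroph	51.7	57
1006	Pedospumella encystans	heterotroph	54.5	42
JBMS11	Pedospumella encystans	heterotroph	51.4	62
JBC07	Poteriospumella lacustris	heterotroph	53.1	69
JBM10	Poteriospumella lacustris	heterotroph	53.1	73
JBNZ41	Poteriospumella lacustris	heterotroph	52.9	71
199hm	Spumella vulgaris	heterotroph	47.9	61
CCAC 4401B	Chromulina nebulosa	mixotroph	43.9	42
FU18K-A	Dinobryon divergens	mixotroph	45.1	74
LO226K-S	Dinobryon pediforme	mixotroph	51.6	31
PR26K-G	Epipyxis sp.	mixotroph	34.1	56
933-7	Chlorochromonas danica	mixotroph	45.4	96
DS	Poterioochromonas malhamensis	mixotroph	40.4	76
WA18K-M	Mallomonas annulata	phototroph	40.1	68
LO234KE	Synura sphagnicola	phototroph	46.9	48
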