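species	phylum	lifestyle	cell_plan
Chlamydia_trachomatis	Chlamydiae	allopatric	non_compartmentalized
Chlamydia_muridarum	Chlamydiae	allopatric	non_compartmentalized
Chlamydia_pneumoniae	Chlamydiae	allopatric	non_compartmentalized
Chlamydia_psittaci	Chlamydiae	allopatric	non_compartmentalized
Chlamydia_abortus	Chlamydiae	allopatric	non_compartmentalized
Chlamydia_caviae	Chlamydiae	allopatric	non_compartmentalized
Chlamydia_felis	Chlamydiae	allopatric	non_compartmentalized
Chlamydia_pecorum	Chlamydiae	allopatric	non_compartmentalized
Simkania_negevensis	Chlamydiae	sympatric	compartmentalized
Waddlia_chondrophila	Chlamydiae	sympatric	unknown
Rhodopirellula_baltica	Planctomycetes	sympatric	compartmentalized
Blastopirellula_marina	Planctomycetes	sympatric	compartmentalized
Pirellula_staleyi	Planctomycetes	sympatric	compartmentalized
Planctomyces_maris	Planctomycetes	sympatric	compartmentalized
Planctomyces_limnophilus	Planctomycetes	sympatric	compartmentalized
Gemmata_obscuriglobus	Planctomycetes	sympatric	compartmentalized
Isosphaera_pallida	Planctomycetes	sympatric	compartmentalized
Kuenenia_stuttgartiensis	Planctomycetes	sympatric	compartmentalized
Akkermansia_muciniphila	Verrucomicrobiae	sympatric	compartmentalized
Akkermansia_glycaniphila	Verrucomicrobiae	sympatric	unknown
Verrucomicrobium_spinosum	Verrucomicrobiae	sympatric	compartmentalized
Rubritalea_marina	Verrucomicrobiae	sympatric	unknown
Opitutus_terrae	Verrucomicrobiae	sympatric	compartmentalized
Opitutaceae_bacterium_TAV2	Verrucomicrobiae	sympatric	unknown
Coraliomargarita_akajimensis	Verrucomicrobiae	sympatric	compartmentalized
Haloferula_sp_BvORR071	Verrucomicrobiae	sympatric	unknown
Methylacidiphilum_infernorum	Verrucomicrobiae	sympatric	compartmentalized
Verrucomicrobiae_bacterium_DG1235	Verrucomicrobiae	sympatric	unknown
Pedosphaera_parvula	Verrucomicrobiae	sympatric	compartmentalized
Chthoniobacter_flavus	Verrucomicrobiae	sympatric	compartmentalized
Lentisphaera_araneosa	Lentisphaerae	sympatric	compartmentalized
Victivallis_vadensis	Lentisphaerae	sympatric	compartmentalized
Lentisphaerae_bacterium_L6	Lentisphaerae	sympatric	compartmentalized
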