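(((((((Chlamydia_trachomatis:0.11,Chlamydia_muridarum:0.10):0.03,Chlamydia_pneumoniae:0.13):0.02,(Chlamydia_psittaci:0.09,Chlamydia_abortus:0.10):0.03):0.02,(Chlamydia_caviae:0.12,Chlamydia_felis:0.11):0.03):0.03,Chlamydia_pecorum:0.16)Chlamydiaceae:0.12,(Simkania_negevensis:0.2,Waddlia_chondrophila:0.2)Waddliaceae:0.1)Chlamydiae_anc:0.18,((((Rhodopirellula_baltica:0.08,Blastopirellula_marina:0.08):0.05,Pirellula_staleyi:0.12):0.06,((Planctomyces_maris:0.1,Planctomyces_limnophilus:0.1):0.05,(Gemmata_obscuriglobus:0.13,Isosphaera_pallida:0.13):0.03):0.04,Kuenenia_stuttgartiensis:0.22)Planctomycetes_anc:0.12,((((Akkermansia_muciniphila:0.12,Akkermansia_glycaniphila:0.12):0.08,(Verrucomicrobium_spinosum:0.14,Rubritalea_marina:0.14):0.06):0.04,((Opitutus_terrae:0.1,Opitutaceae_bacterium_TAV2:0.1):0.07,(Coraliomargarita_akajimensis:0.12,Haloferula_sp_BvORR071:0.12):0.05):0.05,((Methylacidiphilum_infernorum:0.16,Verrucomicrobiae_bacterium_DG1235:0.16):0.04,(Pedosphaera_parvula:0.1,Chthoniobacter_flavus:0.1):0.08):0.04)Verrucomicrobiae_anc:0.1,(Lentisphaera_araneosa:0.15,(Victivallis_vadensis:0.12,Lentisphaerae_bacterium_L6:0.12):0.05)Lentisphaerae_anc:0.14)VL_anc:0.06)PVL_anc:0.08)PVC_root;
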