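# Carbon-backbone construction of proteinogenic amino acids from cytosolic
# central-carbon precursors, as convolution recipes over precursor EMUs.
# Curated from the standard amino-acid biosynthesis atom mappings used in
# 13C flux analysis; editable. Columns: amino_acid, n_carbons, recipe
# (space-separated metabolite:positions parts, positions 1-based).
Gly	2	3pg_c:1,2
Ala	3	pyr_c:1,2,3
Val	5	pyr_c:1,2,3 pyr_c:2,3
Thr	4	oaa_c:1,2,3,4
Leu	6	accoa_c:1,2 pyr_c:2,3 pyr_c:2,3
Ile	6	oaa_c:1,2,3,4 pyr_c:2,3
Asp	4	oaa_c:1,2,3,4
Glu	5	akg_c:1,2,3,4,5
Gln	5	akg_c:1,2,3,4,5
Arg	6	akg_c:1,2,3,4,5 co2_c:1
Phe	9	pep_c:1,2,3 pep_c:2,3 e4p_c:1,2,3,4
Tyr	9	pep_c:1,2,3 pep_c:2,3 e4p_c:1,2,3,4
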