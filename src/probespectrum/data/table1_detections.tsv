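# White-truffle (Tuber magnatum) PCR detection survey, spring 2022-2023.
# One row per (fruiting site, plant species): plant samples analyzed and
# samples positive by species-specific nested PCR.  Counts reconstructed
# from the published per-site totals (60/30/10 analyzed, 15/5/1 positive)
# and per-species percentages; species with no positive samples are
# aggregated per site as "other species".
site	species	n_analyzed	n_positive
CDP	Arum italicum	6	2
CDP	Sison amomum	2	1
CDP	Taraxacum dissectum	2	1
CDP	Galium verrucosum	1	1
CDP	Hedera helix	7	3
CDP	Primula vulgaris	9	3
CDP	Ranunculus bulbosus	4	1
CDP	Urtica dioica	3	2
CDP	Viola odorata	3	1
CDP	other species	23	0
PF	Acer campestre	1	1
PF	Carex pendula	12	4
PF	other species	17	0
MNS	Ajuga reptans	2	1
MNS	other species	8	0
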