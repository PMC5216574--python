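code	species	group	clade	table	tree_tip	pre_atg_exon	pre_atg_intron	atg_exon	ig1_intron	exon3	mini_intron	exon4	n_add_5p	n_add_3p	flags	low_confidence	notes
Hs	Homo sapiens	Chordata (mammals)	gnathostome	1	Hs	302	39985	401	19977	4819	.	.	0	0	.	0	.
Mm	Mus musculus	Chordata (mammals)	gnathostome	1	Mm	139	45369	398	8351	3707	.	.	0	0	.	0	.
Clf	Canis lupus familiaris	Chordata (mammals)	gnathostome	1	Clf	375	48846	383	16520	4968	.	.	0	0	extra_upstream_exon	0	additional pre-ATG exon reported >100 kb upstream
Oa	Ornithorhynchus anatinus	Chordata (mammals)	gnathostome	1	Oa	161	58270	398	30785	5789	.	.	0	0	.	0	.
Dn	Dasypus novemcinctus	Chordata (mammals)	gnathostome	1	Dn	203	62147	400	22513	2403	.	.	0	0	ends_at_stop	0	.
Gg	Gallus gallus	Chordata (aves)	gnathostome	1	Gg	.	.	317	8464	2409	.	.	0	0	.	0	.
Fa	Ficedula albicollis	Chordata (aves)	gnathostome	1	Fa	175	34691	410	12789	2740	.	.	0	0	.	0	.
Ac	Anolis carolinensis	Chordata (reptiles)	gnathostome	1	Ac	392	56285	403	26079	7196	.	.	0	0	.	0	.
Ps	Pelodiscus sinensis	Chordata (reptiles)	gnathostome	1	Ps	.	.	380	25784	6793	.	.	0	0	.	0	.
Xt	Xenopus tropicalis	Chordata (amphibia)	gnathostome	1	Xt	125	19428	354	8686	2917	.	.	0	0	.	0	.
Dr	Danio rerio	Chordata (teleostei)	gnathostome	1	Dr	169	39769	528	14466	2899	.	.	0	0	.	0	.
Gm1	Gadus morhua	Chordata (teleostei)	gnathostome	1	Gm1	.	.	345	1126	2310	.	.	0	0	ends_at_stop	0	.
Xm1	Xiphophorus maculatus	Chordata (teleostei)	gnathostome	1	Xm1	595	8826	566	2800	3850	.	.	0	0	.	0	.
Tr1	Takifugu rubripes	Chordata (teleostei)	gnathostome	1	Tr1	.	.	366	818	2307	.	.	0	0	ends_at_stop	0	.
Cmi	Callorhinchus milii	Chordata (chondrichthyes)	gnathostome	1	Cmi	.	.	276	11246	2373	.	.	0	0	missing_5p,ends_at_stop	0	.
Pm1	Petromyzon marinus	Chordata (cyclostomata)	cyclostome	1	Pm1	172	24308	399	1218	2218	.	.	0	0	ends_at_stop	0	.
Ci	Ciona intestinalis	Urochordata	urochordate	1	Ci	.	.	348	6249	3703	.	.	0	4	.	0	4 additional 3' CDS introns
Bf	Branchiostoma floridae	Cephalochordata	cephalochordate	1	Bf	.	.	708	10023	1653	.	.	2	0	missing_5p,ends_at_stop	0	2 additional large 5' introns
Sk	Saccoglossus kowalevskii	Hemichordata	hemichordate	1	Sk	161	5069	309	7194	5506	.	.	0	0	.	0	.
Spu	Strongylocentrotus purpuratus	Echinodermata	echinoderm	1	Spu	.	.	300	8426	2373	.	.	0	0	ends_at_stop	0	.
Dm	Drosophila melanogaster	Arthropoda (insecta)	arthropod	1	Dm	437	8235	322	284	5774	.	.	0	12	.	0	12 additional 3' introns; IG1 domain lost but IG1-intron position retained
Tc	Tribolium castaneum	Arthropoda (insecta)	arthropod	1	Tc	.	.	192	46	3153	.	.	0	4	missing_5p,ends_at_stop	1	IG1 cell ambiguous: conflicts with stated 47-bp minimum
Dpu	Daphnia pulex	Arthropoda (crustacea)	arthropod	1	Dpu	.	.	723	341	2956	.	.	0	3	.	1	ambiguous cell boundaries
Is	Ixodes scapularis	Arthropoda (chelicerata)	arthropod	1	Is	.	.	111	785	2397	.	.	0	2	missing_5p,ends_at_stop	1	ambiguous cell boundaries; first additional intron within IG1 domain
Ob	Octopus bimaculoides	Mollusca (cephalopoda)	mollusc	1	Ob	561	14288	1383	8418	2310	.	.	0	0	ends_at_stop	0	.
Cg	Crassostrea gigas	Mollusca (bivalvia)	mollusc	1	Cg	.	.	231	3133	2286	.	.	0	0	ends_at_stop	0	.
Lg	Lottia gigantea	Mollusca (gastropoda)	mollusc	1	Lg	.	.	137	3043	2185	.	.	0	0	starts_after_atg,ends_at_stop	0	.
Ct	Capitella teleta	Annelida (sedentaria)	annelid	1	Ct	.	.	210	48	3408	.	.	0	0	.	0	.
Hr	Helobdella robusta	Annelida (clitellata)	annelid	1	Hr	.	.	186	276	2602	.	.	0	0	.	0	.
Ce	Caenorhabditis elegans	Nematoda (chromadorea)	nematode	1	Ce	89	5376	229	328	2236	.	.	0	3	.	0	3 additional 3' introns
Cr	Caenorhabditis remanei	Nematoda (secernentea)	nematode	1	Cr	.	.	216	319	1653	.	.	0	3	.	0	3 additional 3' introns
Hm	Hydra magnipapillata	Cnidaria (hydrozoa)	cnidarian	1	Hm	.	.	210	1751	2189	.	.	0	1	missing_5p	0	1 additional 3' S6 intron
Nv	Nematostella vectensis	Cnidaria (anthozoa)	cnidarian	1	Nv	.	.	162	2567	5553	.	.	0	1	missing_5p,ends_at_stop	0	1 additional 3' S6 intron
Ta	Trichoplax adhaerens	Placozoa	placozoan	1	Ta	.	.	114	320	2559	.	.	1	1	missing_5p,ends_at_stop	0	1 additional 5' and 1 additional 3' intron
Aq	Amphimedon queenslandica	Porifera (demospongiae)	sponge	1	Aq	.	.	170	47	4254	.	.	0	0	missing_5p,ends_at_stop	0	entire CDS in two exons
Gm2	Gadus morhua	Chordata (teleostei)	gnathostome	2	Gm1	.	.	.	.	480	384	1824	0	0	missing_5p,ends_at_stop	0	Dag1a paralogue; 5' region not annotated
Xm2	Xiphophorus maculatus	Chordata (teleostei)	gnathostome	2	Xm1	.	.	210	9155	459	726	1806	0	0	ends_at_stop	0	Dag1a paralogue
Tr2	Takifugu rubripes	Chordata (teleostei)	gnathostome	2	Tr1	.	.	336	2795	403	137	1827	1	0	ends_at_stop	0	Dag1a paralogue; 1 additional 5' intron (uncertain)
Pm2	Petromyzon marinus	Chordata (cyclostomata)	cyclostome	2	Pm1	.	.	159	2684	975	126	1356	0	0	ends_at_stop	0	paralogue; mini-intron in mucin region, not S6
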