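# Synthetic human dystroglycan domain table (fixture convention).
# Feature order follows the canonical domain layout of the DG precursor
# (SP, IG1, S6, mucin, IG2, MAT, NU, TM, Cyto, DBS); the only anchored fact
# is that the 95/96 insertion site lies inside IG1, mid third beta-strand.
# Exact residue ranges are conventions, not measured values.
protein_id	feature	start	end
Hs_DG	SP	1	29
Hs_DG	IG1	50	160
Hs_DG	beta1	58	64
Hs_DG	beta2	74	82
Hs_DG	beta3	91	99
Hs_DG	beta4	107	114
Hs_DG	S6	180	310
Hs_DG	mucin	316	485
Hs_DG	IG2	491	582
Hs_DG	MAT	583	650
Hs_DG	NU	651	711
Hs_DG	TM	712	734
Hs_DG	Cyto	735	895
Hs_DG	DBS	886	895
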