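gene_symbol	cell_type	reported_cluster
Dazl	spermatogonia	1
1500011H22Rik	spermatocytes	2
1700029G01Rik	spermatocytes	3
2410022L05Rik	spermatocytes	2
Akap12	spermatocytes	5
Aldoa-ps1	spermatocytes	4
Atl3	spermatocytes	4
Cypt3	spermatocytes	3
D030056L22Rik	spermatocytes	1
Gsg2	spermatocytes	3
H3f3b	spermatocytes	1
Hnrpa2b1	spermatocytes	1
Lyar	spermatocytes	2
Nt5c1b	spermatocytes	4
Pgk2	spermatocytes	4
Slc2a3	spermatocytes	2
Spert	spermatocytes	4
Stard10	spermatocytes	4
Stmn1	spermatocytes	1
Vkorc1	spermatocytes	5
Acrv1	spermatids	3
Actl7a	spermatids	4
Akap4	spermatids	4
Marcksl1	spermatids	5
Pdpk1	spermatids	4
Pdzk1	spermatids	4
Prm1	spermatids	2
Spag4l	spermatids	3
Tctex1d1	spermatids	4
Tnp2	spermatids	3
Zpbp	spermatids	3
Hsd17b3	leydig	5
Hsd3b1	leydig	5
Cyp17a1	leydig	5
Acta2	ptm	5
Cldn11	sertoli	5
Clu	sertoli	5
Ctsl	sertoli	5
Vim	sertoli	5
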