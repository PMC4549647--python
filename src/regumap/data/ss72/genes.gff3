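##gff-version 3
chrS	regumap	gene	20000	20399	.	+	.	ID=g01
chrS	regumap	mRNA	20000	20399	.	+	.	ID=g01.t1;Parent=g01
chrS	regumap	exon	20000	20099	.	+	.	Parent=g01.t1
chrS	regumap	exon	20200	20399	.	+	.	Parent=g01.t1
chrS	regumap	CDS	20000	20099	.	+	0	Parent=g01.t1
chrS	regumap	CDS	20200	20399	.	+	0	Parent=g01.t1
chrS	regumap	gene	60000	60399	.	+	.	ID=g02
chrS	regumap	mRNA	60000	60399	.	+	.	ID=g02.t1;Parent=g02
chrS	regumap	exon	60000	60099	.	+	.	Parent=g02.t1
chrS	regumap	exon	60200	60399	.	+	.	Parent=g02.t1
chrS	regumap	CDS	60000	60099	.	+	0	Parent=g02.t1
chrS	regumap	CDS	60200	60399	.	+	0	Parent=g02.t1
chrS	regumap	gene	100000	100399	.	+	.	ID=g03
chrS	regumap	mRNA	100000	100399	.	+	.	ID=g03.t1;Parent=g03
chrS	regumap	exon	100000	100099	.	+	.	Parent=g03.t1
chrS	regumap	exon	100200	100399	.	+	.	Parent=g03.t1
chrS	regumap	CDS	100000	100099	.	+	0	Parent=g03.t1
chrS	regumap	CDS	100200	100399	.	+	0	Parent=g03.t1
chrS	regumap	gene	140000	140399	.	+	.	ID=g04
chrS	regumap	mRNA	140000	140399	.	+	.	ID=g04.t1;Parent=g04
chrS	regumap	exon	140000	140099	.	+	.	Parent=g04.t1
chrS	regumap	exon	140200	140399	.	+	.	Parent=g04.t1
chrS	regumap	CDS	140000	140099	.	+	0	Parent=g04.t1
chrS	regumap	CDS	140200	140399	.	+	0	Parent=g04.t1
chrS	regumap	gene	180000	230399	.	+	.	ID=g05
chrS	regumap	mRNA	180000	230399	.	+	.	ID=g05.t1;Parent=g05
chrS	regumap	exon	180000	180199	.	+	.	Parent=g05.t1
chrS	regumap	exon	230200	230399	.	+	.	Parent=g05.t1
chrS	regumap	gene	260000	260999	.	+	.	ID=g06
chrS	regumap	mRNA	260000	260999	.	+	.	ID=g06.t1;Parent=g06
chrS	regumap	exon	260000	260199	.	+	.	Parent=g06.t1
chrS	regumap	exon	260400	260999	.	+	.	Parent=g06.t1
chrS	regumap	CDS	260100	260199	.	+	0	Parent=g06.t1
chrS	regumap	CDS	260400	260701	.	+	0	Parent=g06.t1
chrS	regumap	five_prime_UTR	260000	260099	.	+	.	Parent=g06.t1
chrS	regumap	three_prime_UTR	260702	260999	.	+	.	Parent=g06.t1
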