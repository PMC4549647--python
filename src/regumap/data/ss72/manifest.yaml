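- file: GM12878_PolII.bed
  cell: GM12878
  mark: PolII
- file: GM12878_H3K27Ac.bed
  cell: GM12878
  mark: H3K27Ac
- file: GM12878_H3K36me3.bed
  cell: GM12878
  mark: H3K36me3
- file: GM12878_H3K27me3.bed
  cell: GM12878
  mark: H3K27me3
- file: GM12878_H3K4me1.bed
  cell: GM12878
  mark: H3K4me1
- file: GM12878_H3K4me2.bed
  cell: GM12878
  mark: H3K4me2
- file: GM12878_H3K4me3.bed
  cell: GM12878
  mark: H3K4me3
- file: GM12878_H3K9Ac.bed
  cell: GM12878
  mark: H3K9Ac
- file: GM12878_CTCF.bed
  cell: GM12878
  mark: CTCF
- file: GM12878_DNase.bed
  cell: GM12878
  mark: DNase
- file: CD14_PolII.bed
  cell: CD14
  mark: PolII
- file: CD14_H3K27Ac.bed
  cell: CD14
  mark: H3K27Ac
- file: CD14_H3K36me3.bed
  cell: CD14
  mark: H3K36me3
- file: CD14_H3K27me3.bed
  cell: CD14
  mark: H3K27me3
- file: CD14_H3K4me1.bed
  cell: CD14
  mark: H3K4me1
- file: CD14_H3K4me2.bed
  cell: CD14
  mark: H3K4me2
- file: CD14_H3K4me3.bed
  cell: CD14
  mark: H3K4me3
- file: CD14_H3K9Ac.bed
  cell: CD14
  mark: H3K9Ac
- file: CD14_CTCF.bed
  cell: CD14
  mark: CTCF
- file: CD14_DNase.bed
  cell: CD14
  mark: DNase
- file: A549_PolII.bed
  cell: A549
  mark: PolII
- file: A549_H3K27Ac.bed
  cell: A549
  mark: H3K27Ac
- file: A549_H3K36me3.bed
  cell: A549
  mark: H3K36me3
- file: A549_H3K27me3.bed
  cell: A549
  mark: H3K27me3
- file: A549_H3K4me1.bed
  cell: A549
  mark: H3K4me1
- file: A549_H3K4me2.bed
  cell: A549
  mark: H3K4me2
- file: A549_H3K4me3.bed
  cell: A549
  mark: H3K4me3
- file: A549_H3K9Ac.bed
  cell: A549
  mark: H3K9Ac
- file: A549_CTCF.bed
  cell: A549
  mark: CTCF
- file: A549_DNase.bed
  cell: A549
  mark: DNase
- file: GM12878_TF_NFKB.bed
  cell: GM12878
  mark: NFKB
  kind: tf
- file: GM12878_TF_STAT.bed
  cell: GM12878
  mark: STAT
  kind: tf
- file: GM12878_TF_EGR1.bed
  cell: GM12878
  mark: EGR1
  kind: tf
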