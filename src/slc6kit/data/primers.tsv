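# Published primers for the jellyfish SLC6 transporter work.
# Columns: name, sequence (5'->3', IUPAC), role.
# Primer names of the For_/Rev_ series encode the 1-based cDNA coordinate
# of the primer's 5'-terminal base, so amplicon lengths follow directly as
# rev - fwd + 1 (e.g. For_293/Rev_684 -> 392 bp).
# NOTE: the source methods text prints the name "PA144" twice (once where
# the narrative expects the second phage-arm primer, PA143) with a single
# sequence; the printed sequence is shipped once under PA144 and the
# discrepancy is flagged here rather than silently resolved.
name	seq	role
iNAT6R	GCACAACCGGTCCACTCCRTANANCCA	reverse
PA144	GTATCGGCGGAATTCGTCGA	forward
TR-1	CTGATTGCCTTGTTCCAGGT	forward
TR-2	GGGCTGGGTGGATTTCCTTC	reverse
nuc52-76	ATTGCCAAGACGGAGTCCATCAAGG	forward
For_176	TTTGTCAGAAGAATGGAGGAGGTGC	forward
Rev_757	CCTTTCCGCTGGACTGGATACCTT	reverse
For_293	CCCTCTTGGCATGGAAGGAAA	forward
Rev_684	GAGTTTGGCATTGAGGCCGA	reverse
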