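# Reference codons for the 14 BRAF hydrophobic-pocket / activation-segment
# positions analysed by this package (BRAF kinase-domain author numbering).
# Val600 = GTG and Leu597 = CTG are fixed by the known base-change distances
# of the hotspot substitutions (V600E one base, V600K/D two, V600H and L597Y
# three); every other position defaults to the most frequent human codon for
# its wild-type residue. Override with a user-supplied two-column file.
position	codon
468	TTC
485	CTG
487	GTG
497	GCC
498	TTC
525	CTG
597	CTG
598	GCC
599	ACC
600	GTG
601	AAG
602	AGC
603	CGG
604	TGG
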