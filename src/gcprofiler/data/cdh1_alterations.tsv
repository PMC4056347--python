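sample	group	gene	category	detail	region
D-01	DGC	CDH1	CNV_loss	Loss	Exons 1 to 16
D-02	DGC	CDH1	SNV	N256S	Exon 6
D-02	DGC	CDH1	CNV_loss	Loss	Exons 1 to 16
D-03	DGC	CDH1	SNV	Splice site	Donor site of Intron 4
D-04	DGC	CDH1	CNV_loss	Loss	Exons 1 to 16
D-05	DGC	CDH1	SNV	D257N	Exon 6
D-05	DGC	CDH1	INDEL	S829fs	Exon 16
D-06	DGC	CDH1	none
D-07	DGC	CDH1	none
D-08	DGC	CDH1	none
D-09	DGC	CDH1	SNV	V252G	Exon 6
D-09	DGC	CDH1	SV_breakpoint	Break point	Intron 2
D-10	DGC	CDH1	CNV_loss	Loss	Exons 1 to 16
D-11	DGC	CDH1	CNV_loss	Loss	Exons 1 to 16
D-12	DGC	CDH1	SNV	Q23*	Exon 2
D-13	DGC	CDH1	CNV_loss	Loss	Exons 1 to 16
D-13	DGC	CDH1	SV_breakpoint	Break point	Introns 2 and 10
D-14	DGC	CDH1	SV_breakpoint	Break point	Introns 2, 5 and 9
I-01	IGC	CDH1	CNV_loss	Loss	Exons 1 to 16
I-02	IGC	CDH1	CNV_loss	Loss	Exons 1 to 16
I-03	IGC	CDH1	SNV	D221G	Exon 5
I-03	IGC	CDH1	SV_breakpoint	Break point	Introns 10 and 13
I-04	IGC	CDH1	CNV_loss	Loss	Exons 1 to 16
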