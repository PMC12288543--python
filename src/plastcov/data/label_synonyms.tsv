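raw	harmonized
ga ii	GA II
gaii	GA II
genome analyzer ii	GA II
genome analyzer iix	GA IIx
ga iix	GA IIx
hiseq 1500	HiSeq 1500
hiseq1500	HiSeq 1500
hiseq 2000	HiSeq 2000
hiseq2000	HiSeq 2000
hiseq 2500	HiSeq 2500
hiseq2500	HiSeq 2500
hiseq 4000	HiSeq 4000
hiseq4000	HiSeq 4000
hiseq x ten	HiSeq X Ten
hiseq x	HiSeq X Ten
hiseqx ten	HiSeq X Ten
miseq	MiSeq
nextseq 500	NextSeq 500
nextseq500	NextSeq 500
novaseq 6000	NovaSeq 6000
clc	CLC
clc genomics workbench	CLC
clc gw	CLC
soapdenovo	SOAPdenovo
soapdenovo2	SOAPdenovo
velvet	Velvet
yasra	YASRA
getorganelle	GetOrganelle
get organelle	GetOrganelle
novoplasty	NOVOPlasty
fast-plast	fast-plast
fastplast	fast-plast
org.asm	ORG.asm
orgasm	ORG.asm
spades	SPAdes
abyss	ABySS
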