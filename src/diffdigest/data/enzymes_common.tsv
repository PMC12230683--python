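# Common commercially available restriction enzymes.
# Dialect: name<TAB>site, caret = top-strand cut, (n/m) = outside cut offsets
# past the 3' end of the site. Recognition sites use IUPAC ambiguity codes.
AatII	GACGT^C
AflII	C^TTAAG
AflIII	A^CRYGT
AgeI	A^CCGGT
AlwNI	CAGNNN^CTG
ApaI	GGGCC^C
ApaLI	G^TGCAC
AscI	GG^CGCGCC
AseI	AT^TAAT
AvaI	C^YCGRG
AvrII	C^CTAGG
BamHI	G^GATCC
BclI	T^GATCA
BglII	A^GATCT
BmtI	GCTAG^C
BsaI	GGTCTC(1/5)
BsiWI	C^GTACG
BsmBI	CGTCTC(1/5)
BspEI	T^CCGGA
BspHI	T^CATGA
BsrGI	T^GTACA
BstXI	CCANNNNN^NTGG
ClaI	AT^CGAT
DraI	TTT^AAA
DrdI	GACNNNN^NNGTC
EagI	C^GGCCG
EcoNI	CCTNN^NNNAGG
EcoRI	G^AATTC
EcoRV	GAT^ATC
FseI	GGCCGG^CC
HindIII	A^AGCTT
HpaI	GTT^AAC
KpnI	GGTAC^C
MfeI	C^AATTG
MluI	A^CGCGT
MscI	TGG^CCA
NcoI	C^CATGG
NdeI	CA^TATG
NheI	G^CTAGC
NotI	GC^GGCCGC
NruI	TCG^CGA
NsiI	ATGCA^T
PacI	TTAAT^TAA
PciI	A^CATGT
PmeI	GTTT^AAAC
PspOMI	G^GGCCC
PstI	CTGCA^G
PvuI	CGAT^CG
PvuII	CAG^CTG
SacI	GAGCT^C
SacII	CCGC^GG
SalI	G^TCGAC
SbfI	CCTGCA^GG
ScaI	AGT^ACT
SgrAI	CR^CCGGYG
SmaI	CCC^GGG
SpeI	A^CTAGT
SphI	GCATG^C
SspI	AAT^ATT
StuI	AGG^CCT
SwaI	ATTT^AAAT
XbaI	T^CTAGA
XhoI	C^TCGAG
XmaI	C^CCGGG
XmnI	GAANN^NNTTC
ZraI	GAC^GTC
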