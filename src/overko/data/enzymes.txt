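# Builtin restriction-enzyme table: common commercially available
# Type II enzymes with 4-8 nt recognition sequences.
# Format: Name<whitespace>Recognition ; '#' starts a comment.
# Degenerate positions use IUPAC one-letter ambiguity codes.
AatII   GACGTC
AccI    GTMKAC
AflII   CTTAAG
AgeI    ACCGGT
AluI    AGCT
ApaI    GGGCCC
ApoI    RAATTY
AscI    GGCGCGCC
AseI    ATTAAT
AvaI    CYCGRG
AvrII   CCTAGG
BamHI   GGATCC
BanII   GRGCYC
BclI    TGATCA
BglII   AGATCT
BsrGI   TGTACA
BstBI   TTCGAA
ClaI    ATCGAT
DdeI    CTNAG
DraI    TTTAAA
EagI    CGGCCG
EcoRI   GAATTC
EcoRV   GATATC
Fnu4HI  GCNGC
FspI    TGCGCA
HaeIII  GGCC
HhaI    GCGC
HincII  GTYRAC
HindIII AAGCTT
HinfI   GANTC
HpaI    GTTAAC
HpaII   CCGG
KpnI    GGTACC
MfeI    CAATTG
MluI    ACGCGT
MscI    TGGCCA
MseI    TTAA
NaeI    GCCGGC
NcoI    CCATGG
NdeI    CATATG
NheI    GCTAGC
NotI    GCGGCCGC
NruI    TCGCGA
NsiI    ATGCAT
PacI    TTAATTAA
PmeI    GTTTAAAC
PstI    CTGCAG
PvuI    CGATCG
PvuII   CAGCTG
RsaI    GTAC
SacI    GAGCTC
SacII   CCGCGG
SalI    GTCGAC
SbfI    CCTGCAGG
ScaI    AGTACT
SmaI    CCCGGG
SpeI    ACTAGT
SphI    GCATGC
SspI    AATATT
StuI    AGGCCT
StyI    CCWWGG
SwaI    ATTTAAAT
TaqI    TCGA
XbaI    TCTAGA
XhoI    CTCGAG
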