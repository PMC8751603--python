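# Non-redundant small molecules used across the ten transgene-free reprogramming
# cocktails, with synonyms, functional categories and main bioactivity.
# Categories: epigenetic | signaling | metabolic | other.
canonical_name	synonyms	categories	bioactivity
CHIR99021	C	metabolic	GSK3 inhibitor (promotes glycolytic switch)
RepSox	RepSOX;6;E-616452	signaling	TGFbeta inhibitor (can replace Sox2)
Valproic acid	VPA;V	epigenetic	HDAC inhibitor
Forskolin	F	signaling	cAMP activator (can replace Oct4)
Parnate	T;Tranylcypromine	epigenetic	Inhibitor of LSD1 acting on histone H3
DZNep		epigenetic	Inhibitor of HMT EZH and SAH synthesis
AM 580	AM580	signaling	Nuclear RARalpha selective agonist
EPZ004777		epigenetic	DOT1L histone (H3K79) methyltransferase inhibitor
NaB	Sodium butyrate	epigenetic	HDAC inhibitor
TTNPB		signaling	Synthetic retinoic acid receptor ligand
BrdU	5-bromo-2'-deoxyuridine	epigenetic;other	Synthetic thymidine analog incorporated into DNA (can replace Oct4)
LiCl	Lithium chloride	metabolic	GSK3 inhibitor
SB431542		signaling	TGFbeta inhibitor (can replace RepSox)
Tranilast		signaling	TGFbeta inhibitor (can replace RepSox)
Trichostatin A	TSA	epigenetic	HDAC inhibitor
Li2CO3	Lithium carbonate	metabolic	GSK3 inhibitor
5-aza-dC	5'-aza-dC;5-Aza-2'-deoxycytidine;Decitabine	epigenetic	DNMT inhibitor
SGC0946		epigenetic	DOT1L histone (H3K79) methyltransferase inhibitor
Cyclic pifithrin-a	cyclic pifithrin-alpha	signaling	p53 inhibitor
A-83-01		signaling	TGF-beta receptor inhibitor
Thiazovivin		signaling	Rho kinase (ROCK) inhibitor
PD0325901		signaling	MEK1/MEK2 inhibitor
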