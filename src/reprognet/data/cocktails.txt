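# The ten established transgene-free reprogramming cocktails.
# One block per cocktail: a [name] header followed by one member per line.
# Member spellings follow the published listings verbatim (including the
# RepSOX capitalisation in Cocktail 8); the loader canonicalizes them.

[Cocktail 1 (VC6TF + TTNPB + DZNep)]
Valproic acid
CHIR99021
RepSox
Parnate
Forskolin
DZNep
TTNPB

[Cocktail 2 (NLS)]
NaB
LiCl
SB431542

[Cocktail 3 (VCR)]
Valproic acid
CHIR99021
RepSox

[Cocktail 4 (TLT)]
Trichostatin A
Li2CO3
Tranilast

[Cocktail 5 (BrdUC6F)]
BrdU
CHIR99021
RepSox
Forskolin

[Cocktail 6 (VC6TF + AM 580 + EPZ004777)]
VPA
CHIR99021
RepSox
Parnate
Forskolin
AM 580
EPZ004777

[Cocktail 7 (VC6TF + AM580 + DZNep + 5-aza-dC + SGC0946 + EPZ004777)]
VPA
CHIR99021
RepSox
Parnate
Forskolin
AM 580
DZNep
5-aza-dC
SGC0946
EPZ004777

[Cocktail 8 (VC6TF + DZNep)]
VPA
CHIR99021
RepSOX
Parnate
Forskolin
DZNep

[Cocktail 9 (VC6TF + AM 580 + DZNep)]
VPA
CHIR99021
RepSox
Parnate
Forskolin
AM 580
DZNep

[Cocktail 10 (CNaATP)]
CHIR99021
NaB
cyclic pifithrin-a
A-83-01
Thiazovivin
PD0325901
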