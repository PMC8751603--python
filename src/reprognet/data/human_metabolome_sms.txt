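# Reprogramming small molecules that are also found in the human metabolome
# (28 compounds), one per line.
5'-Azacytidine
5'-Aza-2'-deoxycytidine
7-hydroxyflavone
90-D3 (Vitamin D3)
Apigenin
Caffeic acid
Chlorogenic acid
Curcumin
Dasatinib
Dexamethasone
EGCG
Fisetin
Forskolin
Fru-2,6-P2
Luteolin
N-acetyl-cysteine
Sodium Butyrate
Prostaglandin E2
Quercetin
Rapamycin
Resveratrol
Retinoic acid
SAHA
Spermidine
Valproic acid
Vitamin A (Retinol acetate)
Vitamin C (Ascorbic acid)
Zolpidem
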