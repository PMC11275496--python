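# Published per-codon counts over the 13 protein-coding genes of the
# Myophonus caeruleus mitogenome (GenBank MN564936).  Codons in RNA alphabet.
codon	count
UUU	67
UUC	128
UUA	83
UUG	38
CUU	98
CUC	128
CUA	265
CUG	66
AUU	83
AUC	176
AUA	107
AUG	62
GUU	37
GUC	48
GUA	60
GUG	17
UAU	78
UAC	125
UAA	122
UAG	86
CAU	89
CAC	114
CAA	162
CAG	59
AAU	84
AAC	162
AAA	149
AAG	72
GAU	50
GAC	68
GAA	86
GAG	52
UCU	96
UCC	177
UCA	130
UCG	40
CCU	150
CCC	160
CCA	154
CCG	42
ACU	116
ACC	196
ACA	155
ACG	43
GCU	65
GCC	153
GCA	94
GCG	21
UGU	32
UGC	49
UGA	77
UGG	33
CGU	34
CGC	33
CGA	44
CGG	28
AGU	45
AGC	107
AGA	66
AGG	57
GGU	38
GGC	47
GGA	63
GGG	39
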