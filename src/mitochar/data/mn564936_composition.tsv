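# Published base composition of regions of the Myophonus caeruleus
# mitogenome (GenBank MN564936), percentages of A/C/G/T per region.
region	a_pct	c_pct	g_pct	t_pct
Whole genome	30.06	31.45	14.78	23.71
rrnS	31.22	26.94	21.12	20.71
rrnL	34.39	23.94	20.39	21.28
nad1	26.67	32.75	14.52	26.06
nad2	30.74	34.10	10.85	24.30
cox1	27.79	30.50	17.15	24.56
d-loop	22.32	29.37	17.68	30.63
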