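# Ionizable groups and pKa values (Bjellqvist table, the de-facto standard for
# IPG-strip pI estimation). polarity: "acid" groups carry charge -1 when deprotonated,
# "base" groups +1 when protonated. Residue-letter groups are side chains; N_term and
# C_term apply once per chain. phospho_1/phospho_2 are the two-stage acidic pKas of a
# phosphate monoester, attached per phosphorylated site.
group	polarity	pka
N_term	base	7.50
C_term	acid	3.55
D	acid	4.05
E	acid	4.45
C	acid	9.00
Y	acid	10.00
H	base	5.98
K	base	10.00
R	base	12.00
phospho_1	acid	1.20
phospho_2	acid	6.50
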