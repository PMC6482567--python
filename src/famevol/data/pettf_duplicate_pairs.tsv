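# Published Ka and Ks estimates for the 12 duplicated PeTTF gene pairs of Moso bamboo.
# Columns: pair, gene_a, gene_b, ka, ks
pair	gene_a	gene_b	ka	ks
PeTTF2-10	PeTTF2	PeTTF10	0.19628	0.28456
PeTTF3-23	PeTTF3	PeTTF23	0.3001	0.57003
PeTTF4-21	PeTTF4	PeTTF21	0.40385	0.30886
PeTTF5-14	PeTTF5	PeTTF14	0.24701	0.26566
PeTTF7-16	PeTTF7	PeTTF16	2.05006	1.33589
PeTTF15-26	PeTTF15	PeTTF26	0.37904	0.7751
PeTTF18-32	PeTTF18	PeTTF32	0.22935	0.26615
PeTTF19-25	PeTTF19	PeTTF25	2.3437	1.19812
PeTTF20-22	PeTTF20	PeTTF22	0.03489	0.15364
PeTTF24-31	PeTTF24	PeTTF31	0.06509	0.10698
PeTTF27-30	PeTTF27	PeTTF30	0.03282	0.0955
PeTTF33-35	PeTTF33	PeTTF35	1.26582	0.53139
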