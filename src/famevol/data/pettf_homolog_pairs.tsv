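# Published paralogous (Pe-Pe) and orthologous (Pe-Os) gene pairs of the PeTTF family.
# Columns: id_a, id_b, relation
id_a	id_b	relation
PeTTF2	PeTTF10	paralog
PeTTF3	PeTTF23	paralog
PeTTF4	PeTTF21	paralog
PeTTF5	PeTTF14	paralog
PeTTF7	PeTTF16	paralog
PeTTF15	PeTTF26	paralog
PeTTF18	PeTTF32	paralog
PeTTF19	PeTTF25	paralog
PeTTF20	PeTTF22	paralog
PeTTF24	PeTTF31	paralog
PeTTF27	PeTTF30	paralog
PeTTF33	PeTTF35	paralog
PeTTF3	LOC_Os04g32590	ortholog
PeTTF7	LOC_Os04g40930	ortholog
PeTTF8	LOC_Os04g45940	ortholog
PeTTF9	LOC_Os04g45750	ortholog
PeTTF11	LOC_Os04g51320	ortholog
PeTTF12	LOC_Os04g33300	ortholog
PeTTF13	LOC_Os12g06640	ortholog
PeTTF15	LOC_Os05g48320	ortholog
PeTTF16	LOC_Os05g03740	ortholog
PeTTF17	LOC_Os01g21590	ortholog
PeTTF21	LOC_Os03g02240	ortholog
PeTTF23	LOC_Os02g31160	ortholog
PeTTF26	LOC_Os05g48690	ortholog
PeTTF29	LOC_Os02g33770	ortholog
PeTTF34	LOC_Os10g37240	ortholog
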