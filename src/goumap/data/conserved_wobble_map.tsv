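# Transcription of the published conserved GoU/UoG orientation map for
# eukaryotic tRNA stems (isotype- and position-specific wobble pairs in
# Mammalia (M) and/or Insecta (I)). Isotype "." marks entries whose group
# label is given only graphically in the source figure; anticodon "." marks
# isotype-level entries. One row per (position, orientation, group).
stem	pos5	pos3	orientation	isotype	anticodon	clades
AA	1	72	GoU	.	.	MI
AA	2	71	GoU	.	.	MI
AA	3	70	GoU	Ala	.	MI
AA	3	70	UoG	Leu	.	MI
AA	4	69	UoG	Asp	.	MI
AA	4	69	UoG	Asn	.	MI
AA	5	68	GoU	.	.	MI
AA	5	68	UoG	Trp	.	MI
AA	6	67	GoU	Leu	.	MI
AA	6	67	UoG	Cys	.	MI
AA	7	66	GoU	.	.	MI
D	10	25	GoU	Gly	.	MI
D	10	25	GoU	Pro	.	MI
D	10	25	GoU	Asp	.	MI
D	10	25	GoU	His	.	MI
D	13	22	UoG	Glu	.	MI
D	13	22	UoG	Gln	.	MI
D	13	22	UoG	iMet	.	MI
AC	27	43	GoU	Tyr	.	MI
AC	27	43	GoU	Gly	UCC	MI
AC	27	43	UoG	Cys	.	MI
AC	28	42	UoG	.	.	MI
AC	30	40	GoU	Ala	.	MI
AC	30	40	GoU	Arg	UCU	M
AC	30	40	UoG	Ile	.	MI
T	49	65	GoU	.	.	MI
T	49	65	UoG	.	.	MI
T	50	64	UoG	.	.	MI
T	51	63	UoG	Phe	.	M
T	51	63	UoG	Tyr	.	M
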