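cell_line	tissue	rb1_genetic_status	rb1_functional_status
T-24	bladder	wild-type	+
U-2-OS	bone	wild-type	+
SF268	CNS	wild-type	+
DLD-1	colon	NA	+
HCT-116	colon	wild-type	+
Hep G2	liver	NA	+
NCI-H460	NSCLC	wild-type	+
A549	NSCLC	wild-type	+
UACC-62	melanoma	wild-type	+
MDAH-2774	ovary	NA	+
PANC-1	pancreas	NA	+
SU.86.86	pancreas	NA	+
NCI-N87	stomach	wild-type	+
Hs 746T	stomach	NA	+
KATOIII	stomach	wild-type	+
SCC-25	tongue	wild-type	+
J82	tongue	Δ21 2107-2A > G	-
HeLa S3	bladder	repressed by E7	-
DU-145	cervix	stop: K175*	-
TCCSUP	bladder	deletion: 1696_2787del1092	-
MDA-MB-436	breast	frame shift: G203fs*8	-
MDA-MB-468	breast	deletion: 265_2787del2523	-
SF-539	CNS	deletion: T116fs*8	-
HeLa	cervix	repressed by E7	-
C-33A	cervix	deletion: 4aa in exon2	-
Lu-135	SCLC	frame shift: R661fs*1	-
NCI-H128	SCLC	frame shift: R418fs*2	-
NCI-H1417	SCLC	stop: Y321*	-
NCI-H69	SCLC	stop: E748*	-
NCI-H596	NSCLC	frame shift: R661fs*1	-
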