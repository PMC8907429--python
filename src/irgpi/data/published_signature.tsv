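gene_a	gene_b	coefficient
CD1B	AMHR2	-0.133719837
CD1C	GDNF	-0.006407801
CD1E	NGF	-0.118650926
HLA-C	SPP1	-0.000146032
HSPA6	PI15	-0.006568346
IFNG	NTS	-0.208747404
RELB	NFATC4	-0.001379582
CXCL13	PLAU	-0.042607265
XCL1	FABP6	-0.179318494
SFTPD	CR2	0.248588976
MMP9	NOX4	-0.126050935
RBP7	PRF1	0.040708869
IFIH1	VAV3	-0.601441422
IDO1	CD72	-0.238320598
IDO1	SECTM1	-0.16744787
IRF1	HMOX1	-0.00086748
IRF1	IL1R1	-0.115025852
ZYX	IRF9	0.117305566
TNFAIP3	IL1R1	-0.209151382
HMOX1	IL32	0.199502086
CCR7	IL11	-0.036970847
PTGDR	EGF	-0.088054831
RAC3	NR1D1	0.174898131
CD19	EGF	-0.012058023
INPP5D	IL1R1	-0.014592558
CXCR3	IL11	-0.12999067
EGF	TNFRSF11A	0.254354052
IL33	RARG	-0.27380975
IL7	PRF1	0.062199575
IL20RB	TNFRSF10C	0.049115859
TEK	CD28	0.046180545
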