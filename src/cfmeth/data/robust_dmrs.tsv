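gene	chrom	start_1based	stop_1based	log2fc	padj
TBX3	chr12	114671701	114672000	1.9	0.0006
CCDC26	chr8	129582001	129582300	1.8	0.0074
VAX2	chr2	70907401	70907700	1.9	0.0128
AC007796.1	chr19	31352701	31353000	1.5	0.0044
CTTNBP2	chr7	117792601	117792900	1.7	0.0128
HOXD3	chr2	176163601	176163900	1.7	0.0128
VTI1A	chr10	112815601	112815900	1.6	0.0116
ZFAT	chr8	134687701	134688000	1.5	0.0116
EXT1	chr8	117931801	117932100	1.4	0.0116
POLR2E	chr19	1087801	1088100	1.5	0.0128
DLEU1	chr13	50133001	50133300	1.4	0.0116
TG	chr8	132882901	132883200	1.3	0.0208
CNTLN	chr9	17444101	17444400	1.1	0.0128
MGRN1	chr16	4664101	4664400	1.1	0.0150
ITPKB	chr1	226680901	226681200	0.9	0.0128
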