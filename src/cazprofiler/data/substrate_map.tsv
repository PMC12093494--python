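substrate	activity	ec_number	family
cellulose	cellulase (endo/exo)	3.2.1.4;3.2.1.91	GH6
cellulose	cellulase (endo/exo)	3.2.1.4;3.2.1.91	GH9
cellulose	cellulase (endo/exo)	3.2.1.4;3.2.1.91	GH12
cellulose	cellulase (endo/exo)	3.2.1.4;3.2.1.91	GH44
cellulose	cellulase (endo/exo)	3.2.1.4;3.2.1.91	GH45
cellulose	cellulase (endo/exo)	3.2.1.4;3.2.1.91	GH74
cellulose	cellulase/beta-glucosidase (bifunctional with xylanase)	3.2.1.4;3.2.1.21	GH1
cellulose	cellulase/beta-glucosidase (bifunctional with xylanase)	3.2.1.4;3.2.1.21	GH2
cellulose	cellulase/beta-glucosidase (bifunctional with xylanase)	3.2.1.4;3.2.1.21	GH3
cellulose	cellulase/beta-glucosidase (bifunctional with xylanase)	3.2.1.4;3.2.1.21	GH5
cellulose	cellulase/beta-glucosidase (bifunctional with xylanase)	3.2.1.4;3.2.1.21	GH8
cellulose	cellulase/beta-glucosidase (bifunctional with xylanase)	3.2.1.4;3.2.1.21	GH10
cellulose	cellulase/beta-glucosidase (bifunctional with xylanase)	3.2.1.4;3.2.1.21	GH30
cellulose	cellulase/beta-glucosidase (bifunctional with xylanase)	3.2.1.4;3.2.1.21	GH39
cellulose	cellulase/beta-glucosidase (bifunctional with xylanase)	3.2.1.4;3.2.1.21	GH51
cellulose	cellulase/beta-glucosidase (bifunctional with xylanase)	3.2.1.4;3.2.1.21	GH116
cellulose	endochitinase-overlapping cellulase	3.2.1.4	GH48
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH1
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH2
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH3
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH5
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH8
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH10
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH30
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH39
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH43
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH51
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH52
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH67
xylan	xylanase/beta-xylosidase	3.2.1.8;3.2.1.37	GH116
xylan	acetyl xylan esterase / feruloyl esterase	3.1.1.72;3.1.1.73	CE1
xylan	acetyl xylan esterase / feruloyl esterase	3.1.1.72;3.1.1.73	CE4
xylan	acetyl xylan esterase / feruloyl esterase	3.1.1.72;3.1.1.73	CE7
lignin	laccase	1.10.3.2	AA1
lignin	lignin peroxidase	1.11.1.14	AA2
starch	alpha-amylase	3.2.1.1	GH13
starch	alpha-amylase	3.2.1.1	GH57
starch	alpha-amylase	3.2.1.1	GH119
starch	beta-amylase	3.2.1.2	GH14
starch	gamma-amylase (glucoamylase)	3.2.1.3	GH15
starch	gamma-amylase (glucoamylase)	3.2.1.3	GH97
chitin	endochitinase	3.2.1.14	GH18
chitin	endochitinase	3.2.1.14	GH19
chitin	endochitinase	3.2.1.14	GH23
chitin	endochitinase	3.2.1.14	GH48
dextran	dextranase	3.2.1.11	GH49
dextran	dextranase	3.2.1.11	GH66
dextran	glucan-1,6-alpha-D-glucosidase	3.2.1.70	GH13
dextran	glucan-1,6-alpha-D-glucosidase	3.2.1.70	GH15
dextran	glucan-1,6-alpha-isomaltosidase	3.2.1.94	GH27
fructan	fructan exohydrolase	3.2.1.80	GH32
pectin	pectin methylesterase	3.1.1.11	CE8
pectin	endo-polygalacturonase	3.2.1.15	GH28
pectin	pectin lyase	4.2.2.10	PL1
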