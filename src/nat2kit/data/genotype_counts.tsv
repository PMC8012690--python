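population	genotype	count
Japanese	*4/*4	480
Japanese	*4/*5	23
Japanese	*4/*6	260
Japanese	*4/*7	125
Japanese	*5/*5	0
Japanese	*5/*6	5
Japanese	*5/*7	2
Japanese	*6/*6	42
Japanese	*6/*7	44
Japanese	*7/*7	9
AFR	*4/*4	134
AFR	*4/*5	163
AFR	*4/*6	134
AFR	*4/*7	19
AFR	*5/*5	62
AFR	*5/*6	92
AFR	*5/*7	7
AFR	*6/*6	38
AFR	*6/*7	12
AFR	*7/*7	0
AMR	*4/*4	50
AMR	*4/*5	84
AMR	*4/*6	33
AMR	*4/*7	29
AMR	*5/*5	52
AMR	*5/*6	46
AMR	*5/*7	17
AMR	*6/*6	13
AMR	*6/*7	14
AMR	*7/*7	9
EAS	*4/*4	157
EAS	*4/*5	16
EAS	*4/*6	115
EAS	*4/*7	86
EAS	*5/*5	1
EAS	*5/*6	15
EAS	*5/*7	5
EAS	*6/*6	40
EAS	*6/*7	48
EAS	*7/*7	21
EUR	*4/*4	34
EUR	*4/*5	107
EUR	*4/*6	66
EUR	*4/*7	6
EUR	*5/*5	108
EUR	*5/*6	117
EUR	*5/*7	12
EUR	*6/*6	48
EUR	*6/*7	5
EUR	*7/*7	0
SAS	*4/*4	29
SAS	*4/*5	75
SAS	*4/*6	74
SAS	*4/*7	13
SAS	*5/*5	63
SAS	*5/*6	117
SAS	*5/*7	21
SAS	*6/*6	65
SAS	*6/*7	31
SAS	*7/*7	1
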