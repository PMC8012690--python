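drug	genotype	activity_score	phenotype
AGT	*4/*4	2.000	RA
AGT	*4/*5	1.178	IA
AGT	*4/*6	1.062	IA
AGT	*4/*7	1.049	IA
AGT	*5/*5	0.356	SA
AGT	*5/*6	0.240	SA
AGT	*5/*7	0.226	SA
AGT	*6/*6	0.125	SA
AGT	*6/*7	0.111	SA
AGT	*7/*7	0.097	SA
DDP	*4/*4	2.000	RA
DDP	*4/*5	1.232	IA
DDP	*4/*6	1.151	IA
DDP	*4/*7	1.782	RA
DDP	*5/*5	0.465	SA
DDP	*5/*6	0.383	SA
DDP	*5/*7	1.014	IA
DDP	*6/*6	0.302	SA
DDP	*6/*7	0.933	IA
DDP	*7/*7	1.564	RA
HLZ	*4/*4	2.000	RA
HLZ	*4/*5	1.272	IA
HLZ	*4/*6	1.088	IA
HLZ	*4/*7	1.034	IA
HLZ	*5/*5	0.544	SA
HLZ	*5/*6	0.360	SA
HLZ	*5/*7	0.306	SA
HLZ	*6/*6	0.175	USA
HLZ	*6/*7	0.121	USA
HLZ	*7/*7	0.067	USA
INH	*4/*4	2.000	RA
INH	*4/*5	1.124	IA
INH	*4/*6	1.039	IA
INH	*4/*7	1.026	IA
INH	*5/*5	0.248	SA
INH	*5/*6	0.163	SA
INH	*5/*7	0.150	SA
INH	*6/*6	0.079	SA
INH	*6/*7	0.066	SA
INH	*7/*7	0.052	SA
PZ	*4/*4	2.000	RA
PZ	*4/*5	1.315	IA
PZ	*4/*6	1.140	IA
PZ	*4/*7	1.058	IA
PZ	*5/*5	0.630	SA
PZ	*5/*6	0.455	SA
PZ	*5/*7	0.373	SA
PZ	*6/*6	0.279	USA
PZ	*6/*7	0.198	USA
PZ	*7/*7	0.116	USA
PA	*4/*4	2.000	RA
PA	*4/*5	1.293	IA
PA	*4/*6	1.191	IA
PA	*4/*7	1.149	IA
PA	*5/*5	0.586	SA
PA	*5/*6	0.484	SA
PA	*5/*7	0.442	SA
PA	*6/*6	0.382	SA
PA	*6/*7	0.340	SA
PA	*7/*7	0.298	SA
SMZ	*4/*4	2.000	RA
SMZ	*4/*5	1.129	IA
SMZ	*4/*6	1.071	IA
SMZ	*4/*7	1.304	IA
SMZ	*5/*5	0.258	USA
SMZ	*5/*6	0.200	USA
SMZ	*5/*7	0.433	SA
SMZ	*6/*6	0.142	USA
SMZ	*6/*7	0.374	SA
SMZ	*7/*7	0.607	SA
SP	*4/*4	2.000	RA
SP	*4/*5	1.229	IA
SP	*4/*6	1.120	IA
SP	*4/*7	1.458	IA
SP	*5/*5	0.457	SA
SP	*5/*6	0.349	SA
SP	*5/*7	0.686	SA
SP	*6/*6	0.241	SA
SP	*6/*7	0.578	SA
SP	*7/*7	0.916	IA
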