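abbreviation	phrase	doc_freq	tfidf
FMA	fugl-meyer assessment	248	8.967532517
Ashworth	ashworth scale	138	14.86100317
BI	barthel index	115	21.46757397
ARAT	action research arm test	81	12.07425711
WMFT	wolf motor function test	75	13.60741523
RS	rankin scale	55	19.33877467
FIM	functional independence measure	42	15.96626141
MOM	main outcome measure	41	5.37136245
MI	motricity index	40	7.990027148
SIAS	stroke impact scale	25	11.18520612
BBS	berg balance scale	23	24.26706778
MAS	motor assessment scale	22	14.7664421
RMA	rivermead motor assessment	20	17.80426457
AAI	arm index	14	12.81320984
BBT	box and block test	14	9.018969872
FAT	frenchay arm test	13	18.36081387
NIHSS	nihss score	12	15.94629694
POM	primary outcome measure	11	5.529408988
JTTHF	jebsen-taylor test of hand function	8	15.01043442
DAS	disability assessment scale	8	14.62921899
BRUNSTROM	brunnstrom scale	7	9.218846945
COPM	canadian occupational performance measure	7	13.53841027
NHPT	nine hole peg test	7	16.42409311
VAS	visual analog scale	7	7.112188973
RS	rankin scale	7	19.33877467
AMAT	arm motor ability test	6	10.48555474
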