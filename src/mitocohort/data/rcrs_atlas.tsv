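# Default rCRS (NC_012920.1) interval atlas. 1-based inclusive coordinates;
# start > end denotes a span wrapping through 16569 -> 1 on the circular genome.
# Top-level partition (categories CR / gene / rRNA / tRNA / non_coding) tiles
# 1..16569 with no overlap: where canonical gene annotations overlap by a few
# bases (MT-TI/MT-TQ, MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4, MT-TC/MT-TY), the
# overlap is assigned to the earlier locus and the later locus starts after it.
# HV and functional-domain spans follow MITOMAP conventions; control-region
# functional domains other than ETAS2 (16294-16357) are reconstructions from
# the cited literature and are editable. Structure elements are approximate
# reconstructions except C, J and K, which are anchored to published spans.
# HSP1/HSP2 promoters are not bundled (not part of the four reported domain
# groups; HSP2 lies outside the control region).
label	category	start	end
CR	CR	16024	576
MT-TF	tRNA	577	647
MT-RNR1	rRNA	648	1601
MT-TV	tRNA	1602	1670
MT-RNR2	rRNA	1671	3229
MT-TL1	tRNA	3230	3304
NC_ND1u	non_coding	3305	3306
MT-ND1	gene	3307	4262
MT-TI	tRNA	4263	4331
MT-TQ	tRNA	4332	4400
NC_TQd	non_coding	4401	4401
MT-TM	tRNA	4402	4469
MT-ND2	gene	4470	5511
MT-TW	tRNA	5512	5579
NC_TWd	non_coding	5580	5586
MT-TA	tRNA	5587	5655
NC_TAd	non_coding	5656	5656
MT-TN	tRNA	5657	5729
NC_OL	non_coding	5730	5760
MT-TC	tRNA	5761	5826
MT-TY	tRNA	5827	5891
NC_CO1u	non_coding	5892	5903
MT-CO1	gene	5904	7445
MT-TS1	tRNA	7446	7514
NC_TS1d	non_coding	7515	7517
MT-TD	tRNA	7518	7585
MT-CO2	gene	7586	8269
NC_CO2d	non_coding	8270	8294
MT-TK	tRNA	8295	8364
NC_TKd	non_coding	8365	8365
MT-ATP8	gene	8366	8572
MT-ATP6	gene	8573	9207
MT-CO3	gene	9208	9990
MT-TG	tRNA	9991	10058
MT-ND3	gene	10059	10404
MT-TR	tRNA	10405	10469
MT-ND4L	gene	10470	10766
MT-ND4	gene	10767	12137
MT-TH	tRNA	12138	12206
MT-TS2	tRNA	12207	12265
MT-TL2	tRNA	12266	12336
MT-ND5	gene	12337	14148
MT-ND6	gene	14149	14673
MT-TE	tRNA	14674	14742
NC_CYBu	non_coding	14743	14746
MT-CYB	gene	14747	15887
MT-TT	tRNA	15888	15953
NC_TTd	non_coding	15954	15955
MT-TP	tRNA	15956	16023
HV1	HV	16024	16383
HV2	HV	57	372
HV3	HV	438	574
ETAS1	functional_domain	16157	16218
ETAS2	functional_domain	16294	16357
CENTRAL_DOMAIN	functional_domain	16384	212
CSB1	functional_domain	213	235
CSB2	functional_domain	299	315
CSB3	functional_domain	346	363
LSP	functional_domain	392	445
SSE_A	structure_element	16079	16119
SSE_B	structure_element	16137	16169
SSE_C	structure_element	16294	16335
SSE_D	structure_element	16368	16409
SSE_E	structure_element	16441	16480
SSE_F	structure_element	16509	16545
SSE_G	structure_element	16550	20
SSE_H	structure_element	30	60
SSE_I	structure_element	73	106
SSE_J	structure_element	116	149
SSE_K	structure_element	181	226
SSE_L	structure_element	243	280
SSE_M	structure_element	303	345
HP_66	homopolymer	66	71
HP_300	homopolymer	300	316
HP_513	homopolymer	513	525
HP_3106	homopolymer	3106	3107
HP_5892	homopolymer	5892	5892
HP_12418	homopolymer	12418	12425
HP_16182	homopolymer	16182	16194
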