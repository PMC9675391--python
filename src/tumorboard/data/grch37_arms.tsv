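chrom	arm	start	end
1	1p	0	121535434
1	1q	124535434	249250621
2	2p	0	92326171
2	2q	95326171	243199373
3	3p	0	90504854
3	3q	93504854	198022430
4	4p	0	49660117
4	4q	52660117	191154276
5	5p	0	46405641
5	5q	49405641	180915260
6	6p	0	58830166
6	6q	61830166	171115067
7	7p	0	58054331
7	7q	61054331	159138663
8	8p	0	43838887
8	8q	46838887	146364022
9	9p	0	47367679
9	9q	50367679	141213431
10	10p	0	39254935
10	10q	42254935	135534747
11	11p	0	51644205
11	11q	54644205	135006516
12	12p	0	34856694
12	12q	37856694	133851895
13	13p	0	16000000
13	13q	19000000	115169878
14	14p	0	16000000
14	14q	19000000	107349540
15	15p	0	17000000
15	15q	20000000	102531392
16	16p	0	35335801
16	16q	38335801	90354753
17	17p	0	22263006
17	17q	25263006	81195210
18	18p	0	15460898
18	18q	18460898	78077248
19	19p	0	24681782
19	19q	27681782	59128983
20	20p	0	26369569
20	20q	29369569	63025520
21	21p	0	11288129
21	21q	14288129	48129895
22	22p	0	13000000
22	22q	16000000	51304566
X	Xp	0	58632012
X	Xq	61632012	155270560
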