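chrom	length	centromere_pos
1	230218	151465
2	813184	238207
3	316620	114385
4	1531933	449711
5	576874	151987
6	270161	148510
7	1090940	496920
8	562643	105586
9	439888	355629
10	745751	436307
11	666816	440129
12	1078177	150828
13	924431	268031
14	784333	628758
15	1091291	326584
16	948066	555957
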