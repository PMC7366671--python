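no,contact,D2L,D3L,D2L_group,D3L_group
1,LH3B-A5H1',-,weak,,
2,LH3B-A5H8,medium,weak,,
3,LH3B-T4H1',weak,medium,,
4,LH3B-T4H2'',strong,strong,,
5,LH3B-T4H3',-,weak,,
6,LH3B-T4H6,weak,weak,,
7,LH3B-T4CH3,-,weak,,
8,LH4A-A5H2,-,weak,,
9,LH4B-A5H4',-,weak,,
10,LH4B-A5H8,-,weak,,
11,LH7A-A5H1',-,weak,,
12,LH7A-A5H8,weak,weak,,
13,LH7A-T4H6,medium,weak,,
14,LH7A-T4CH3,medium,weak,,
15,LH7A-T4H1',medium,medium,,
16,LH7A-T4H2',strong,strong,,a
17,LH7A-T4H2'',strong,strong,,a
18,LH7A-T4H3',weak,-,,
19,LH9A-T4CH3,strong,strong,,
20,LH10A-T4CH3,weak,weak,,
21,LH15A-A5H2,weak,weak,,
22,LH15B-A5H1',-,medium,,
23,LH15B-A5H2,weak,weak,,
24,LH15B-A5H4',-,medium,,
25,LH17A-A5H2,strong,medium,,
26,LH17B-A5H2,strong,medium,,
27,LH17B-A5H4',-,medium,,
28,LH18A-A5H2,strong,weak,,
29,LH18B-A5H1',-,medium,,
30,LH18B-A5H2,strong,medium,,
31,LH18A-A3H2,strong,-,b,
32,LH18B-A3H2,strong,-,b,
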