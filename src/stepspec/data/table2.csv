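codename,sequence,affinity,stoichiometry,direct_sites,binding_steps,missed_steps
D1,CCCGGG,weak,1:1,,CG/CG,CC/GG
D2,CGATATCG,strong,1:1,TA/TA,TA/TA,CG/CG;GA/TC;AT/AT
D3,CCCTAGGG,very strong,1:1,TA/TA,TA/TA,CC/GG;CT/AG
D4,GGGTACCC,strong,1:1,TA/TA,TA/TA,GG/CC;GT/AC
D5,CCCATGGG,medium,1:1,,TG/CA,CC/GG;AT/AT
D6,GGGATCCC,none,,,,GG/CC;GA/TC;AT/AT
D7,GTACGTAC,strong,1:2,,TA/TA,GT/AC;CG/CG
D8,CTAGCTAG,strong,1:2,,TA/TA,CT/AG;GC/GC
D9,GAACGTTC,very weak,1:1,,CG/CG,GA/TC;AA/TT;AC/GT
D10,CGATGCATCG,medium-strong,1:1;1:2,,TG/CA,CG/CG;GA/TC;AT/AT;GC/GC
D11,CGTAGCTACG,strong,1:2,,TA/TA,CG/CG;GT/AC;AG/CT;GC/GC
D12,CTGACGTCAG,medium,1:2,,TG/CA,CT/AG;GA/TC;AC/GT;CG/CG
D13,CTAGCGCTAG,medium-strong,1:2,,TA/TA,CT/AG;AG/CT;GC/GC;CG/CG
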