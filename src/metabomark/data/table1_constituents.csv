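no,name,formula,mz,adduct,fragment_ions,rt,scabra,rigescens,compound_class
1,Secologanic acid,C_16_H_22_O_10_,373.11,[M-H],179/108/204/282,8.40,,+,iridoid
2,Longanic acid,C_16_H_24_O_10_,375.13,[M-H],371/179,2.35,+,,iridoid
3,Gentiolactone,C_10_H_12_O_5_,211.10,[M-H],167,7.50,+,+,iridoid
4,Gentiopicroside,C_16_H_20_O_9_,401.11,[M-H+HCOOH],179/355/149/119,5.22,+,+,iridoid
5,Sweroside,C_16_H_22_O_9_,403.12,[M-H+HCOOH],357/195/179/125,5.63,+,+,iridoid
6,8-epikingside,C_17_H_24_O_11_,403.12,[M-H],371/223/179,7.49,+,,iridoid
7,Caryptoside,C_17_H_26_O_11_,405.14,[M-H+HCOOH],179,2.26,+,+,iridoid
8,Swertiamarin,C_16_H_22_O_10_,419.12,[M-H+HCOOH],179/355/211/119,3.85,+,+,iridoid
9,Loganin,C_17_H_26_O_10_,435.22,[M-H+HCOOH],389.22,7.17,,+,iridoid
10,Secoxyloganin,C_17_H_24_O_11_,449.13,[M-H+HCOOH],179/241/359/403,2.66,+,,iridoid
11,Morroniside,C_17_H_26_O_11_,451.14,[M-H+HCOOH],405/243/179/,2.94,+,,iridoid
12,"2'-O-(2,3-dihyrben)-gentiopicroside",C_20_H_28_O_14_,491.14,[M-H],167/323/459,4.59,+,+,iridoid
13,"2'-O-(2,3-dihyben)-swertamairn",C_23_H_26_O_13_,509.13,[M-H],153/297/315/367,10.53,,+,iridoid
14,"3'-O-(2,3-dihyben)-swertamairn",C_23_H_26_O_13_,509.22,[M-H],153/517/411/321,6.11,,+,iridoid
15,Deglu-noneacetylate-rindoiside,C_23_H_26_O_13_,509.22,[M-H],153/297/315/367,9.53,,+,iridoid
16,Rigenolide A,C_25_H_28_O_12_,519.15,[M-H],307,11.20,,+,iridoid
17,4-glu+D97RT,C_26_H_34_O_11_,521.20,[M-H],359/329,9.44,,+,iridoid
18,Lacriciresinol,C_26_H_34_O_11_,521.20,[M-H],473/355/375/415,15.26,,+,iridoid
19,6'-O-d-glu swertiamarin,C_25_H_28_O_13_,535.14,[M-H],409/491/153/339,14.39,+,,iridoid
20,6'-O-d-glu-Loganic acid,C_22_H_34_O_15_,537.18,[M-H],213,2.05,+,+,iridoid
21,Dideacetylate-deglu-rindoside,C_25_H_28_O_14_,551.14,[M-H],491/409/509,12.34,,+,iridoid
22,Gentianaside,C_22_H_36_O_13_,553.13,[M-H+HCOOH],507,5.03,+,,iridoid
23,6-O-d-glu-gentiopicroside,C_22_H_30_O_14_,563.16,[M-H+HCOOH],341/517,5.69,+,+,iridoid
24,Tortoside B,C_28_H_38_O_13_,581.15,[M-H],401/357/313/269,1.47,,+,iridoid
25,Gentiabavaroside,C_26_H30O_15_,581.16,[M-H],401/357/313/221,1.47,+,,iridoid
26,6-O-d-glu-swertianmarin,C_22_H_32_O_15_,581.17,[M-H+HCOOH],341/535/517/179,2.83,+,,iridoid
27,Deacetylate-deglu-rindoside,C_27_H_30_O_15_,593.15,[M-H],451/531/551,19.54,+,+,iridoid
28,Deglu-trifloroside,C_29_H_32_O_15_,619.17,[M-H],577,24.5,+,+,iridoid
29,Deglu-gelidoside,C_29_H_32_O_16_,635.16,[M-H],551/451/593,23.19,+,+,iridoid
30,Gentiotrifloroside,C_29_H_36_O_17_,655.19,[M-H],315/493/529,7.41,+,+,iridoid
31,Deglu-scabraside,C_34_H_34_O_15_,681.18,[M-H],639/475/153,28.45,+,+,iridoid
32,Gentrigeoside A,C_36_H_60_O_12_,683.40,[M-H],640/622,28.46,+,,iridoid
33,"2,3-deacetyl-trifloroside",C_32_H_40_O_17_,695.18,[M-H],315,13.78,+,,iridoid
34,6'-O-ace-3-O-glu-2-hy-sweroside,C_31_H_38_O_18_,697.17,[M-H],315/535/571/315,14.25,+,,iridoid
35,Trideacetylate-trifloroside,C_31_H_38_O_18_,697.18,[M-H+HCOOH],505/651/313/269,8.78,,+,iridoid
36,Scabran G3,C_28_H_40_O_19_,725.21,[M-H],341/383/503/679,2.55,+,+,iridoid
37,2-deaceyl-trifloroside,C_33_H_38_O_19_,737.19,[M-H],315/575/693,16.1,+,,iridoid
38,Dedihydroxybenzoate-Macrophylloside,C_33_H_40_O_19_,739.20,[M-H],697/577/613/535,15.76,+,+,iridoid
39,Deacetylate-Trifloroside,C_33_H_40_O_19_,739.20,[M-H],697/577/613/535,14.7,+,+,iridoid
40,Deacetylate-Rindoside,C_33_H_40_O_20_,755.20,[M-H],593/315/713,13.92,+,+,iridoid
41,Trifloroside,C_35_H_42_O_20_,781.22,[M-H],619/739/577/315,18.44,+,,iridoid
42,Dideacetylate-Macophylloside,C_36_H_40_O_20_,791.24,[M-H],521/629/315,15.11,+,,iridoid
43,Rindoside,C_35_H_42_O_21_,797.21,[M-H],315/493/635/755,17.19,+,+,iridoid
44,Deacetylate-scabraside,C_38_H_42_O_19_,801.22,[M-H],639/597,18.41,+,,iridoid
45,Acetylate-trifloroside,C_37_H_44_O_21_,823.23,[M-H],619/577/781,21.59,+,,iridoid
46,Deacetylatemacrophylloside A,C_38_H_42_O_21_,833.21,[M-H],671/697/535/315,15.33,+,+,iridoid
47,Scabraside,C_40_H_44_O_20_,843.24,[M-H],681/639/315/801,21.66,+,+,iridoid
48,Dideacetylate-4'-glu-trifloroside,C_37_H_48_O_23_,859.23,[M-H],697,19.31,+,+,iridoid
49,Macrophylloside A,C_40_H_44_O_22_,875.22,[M-H],739/577/535,18.74,+,+,iridoid
50,Deacetylate-4'-glu-trifloroside,C_39_H_50_O_24_,901.26,[M-H],577/459/535/859,13.36,+,,iridoid
51,4-O-beta-d-trifloroside,C_41_H_52_O_25_,943.27,[M-H],459/619/901/577,16.29,+,+,iridoid
52,Acetylate-4'-glu-scabraside,C_46_H_54_O_25_,1005.29,[M-H],963/681/639/477,20.73,+,,iridoid
53,4''-O-beta-d-glucopyranosy1-6'-O-(4-O-beta-d-glu-caffeoyl) linearroside,C_46_H_56_O_25_,1007.30,[M-H],845/801/487/639,11.59,+,,iridoid
54,Benzoxy-4''-O-beta-d-glucopyranosy1-6'-O-(4-O-beta-d-glucopyranosylcaffeoyl)linearroside,C_53_H_60_O_26_,1111.33,[M-H],845/487/639/801,15.03,+,,iridoid
55,Isovitexin,C_21_H_20_O_10_,431.10,[M-H],,9.7,+,+,flavonoid
56,Isoorientin(Homoorientin),C_21_H_20_O_11_,447.15,[M-H],327/357/429,8.29,+,+,flavonoid
57,Isoscoparin,C_22_H_22_O_11_,507.17,[M-H+COOH],461,6.66,,+,flavonoid
58,2-glu-isovitexin,C_27_H_30_O_15_,593.15,[M-H],551/451/531/409,19.54,+,,flavonoid
59,Isosaponarin,C_27_H_30_O_16_,593.15,[M-H],311/431/473/503,7.68,,+,flavonoid
60,Saponarin,C_27_H_30_O_17_,593.15,[M-H],367,11.51,,+,flavonoid
61,4'-glu-isoorientin,C_27_H_30_O_16_,609.14,[M-H],447,5.27,,+,flavonoid
62,Lutonarin,C_27_H_30_O_16_,609.14,[M-H],447/519/489/327,6.87,,+,flavonoid
63,Rutin,C_27_H_30_O_16_,609.14,[M-H],447/519/489/327,6.9,,+,flavonoid
64,Keampferol,C_15_H_10_O_6_,331.04,[M-H+HCOOH],285/165,22.50,+,,flavonoid
65,7-glu-isopyrenine,C_29_H_34_O_17_,653.17,[M-H],315,10.06,+,+,flavonoid
66,Hyperoside,C_21_H_20_O_12_,509.22,[M-H+HCOOH],463,8.95,+,,flavonoid
67,Lonicerin,C_27_H_30_O_15_,593.19,[M-H],551/451,17.06,+,,flavonoid
68,Caffeic acid,C_9_H_8_O_4_,179.03,[M-H],135/109,9.25,+,+,miscellaneous
69,Ferulic acid,C_10_H_10_O_4_,193.02,[M-H],149,3.77,+,,miscellaneous
70,Isoferulic acid,C_10_H_10_O_4_,193.02,[M-H],149,4.01,+,,miscellaneous
71,Vanilloloside,C_13_H_16_O_9_,315.07,[M-H],153,1.6,+,+,miscellaneous
72,"Glu-2,3-dihydroxybenzoic acid",C_14_H_20_O_8_,315.11,[M-H],187/297/253/145,22.81,+,,miscellaneous
73,Glu-2-hydro-3-methoben,C_14_H_18_O_9_,329.09,[M-H],167,6.89,+,+,miscellaneous
74,Methyl-3-(beta-d-glucopyranosyl)-2-hydroxybenzoate,C_14_H_18_O_9_,329.23,[M-H],209/311,19.25,+,,miscellaneous
75,Glu-caffeic acid,C_15_H_18_O_9_,341.09,[M-H],179/135/203/239,1.97,,+,miscellaneous
76,Syringin,C_17_H_24_O_9_,371.10,[M-H],249,4.7,+,,miscellaneous
77,3-[(6-O-Arabinopyranosyl)-beta-d-glucopyranosyloxy]oct-1-en,C_19_H_34_O_10_,421.20,[M-H],289/133,12.57,+,,miscellaneous
78,Methyl-3-[(6-O-beta-d-glucopyranosyl)-beta-d-glucopyranosyloxy]-2-hydroxybenzoate,C_23_H_24_O_12_,491.12,[M-H],153/315/475,12.31,,+,miscellaneous
79,(+) Syringaresinol,C_24_H_30_O_8_,491.14,[M-H+HCOOH],315/447/153,9.94,,+,miscellaneous
80,Lonicerin,C_27_H_30_O_15_,593.19,[M-H],551/451/,16.68,,+,miscellaneous
81,Mangiferin,C_19_H_18_O_11_,421.08,[M-H],403/331/301,5.98,+,,xanthone
82,Gentianabavaroside,C_26_H_30_O_15_,581.16,[M-H],401/357/313/,3.71,+,,xanthone
83,Gentrigeoside D,C_36_H_60_O_13_,745.40,[M-H+HCOOH],699,11.99,,+,triterpenoid
84,Gentrigeoside C,C_42_H_70_O_17_,845.24,[M-H],683/803,21.77,+,,triterpenoid
85,Glu-Gentigeoside C,C_46_H_56_O_25_,1007.31,[M-H],845/801/639/487,11.52,+,,triterpenoid
86,Gentrigeoside A (Dammarane),C_36_H_60_O_12_,683.40,[M-H],640/622,28.46,+,,triterpenoid
87,Rha-Gentrigeoside,C_46_H_54_O_27_,1037.51,[M-H+HCOOH],991,13.6,+,,triterpenoid
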