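no,name,formula,rt,mz,adduct,fragment_ions
1,(+)Syringaresinol,C_24_H_30_O_8_,9.94,491.14,[M-H+HCOOH],315/447/153
2,Lutonarin,C_27_H_30_O_16_,6.87,609.14,[M-H],447/519/489/327
3,Trifloroside,C_35_H_42_O_20_,18.44,781.22,[M-H],619/739/577/315
4,4-beta-d-glu-trifloroside,C_41_H_52_O_25_,16.29,943.27,[M-H],459/619/901/577
5,4''-O-beta-d-glucopyranosy1-6'-O-(4-O-beta-d-glucopyranosylcaffeoyl)linearroside,C_46_H_56_O_25_,11.59,1007.30,[M-H],845/323/487/639/801
6,Macrophylloside A,C_40_H_44_O_22_,18.74,875.22,[M-H],739/577/535
7,Scabraside,C_40_H_44_O_20_,21.66,843.24,[M-H],681/639/315/801
8,Unknown,,25.12,717.46,,
9,Unknown,,15.11,1105.32,,
10,Unknown,,19.00,891.22,,
11,Unknown,,15.63,1053.27,,
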