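index,name,formula,adduct,printed_mz,computed_mz,abs_error,flagged
1,(+)Syringaresinol,C_24_H_30_O_8_,[M-H+HCOOH],491.14,491.1923,0.05,True
2,Lutonarin,C_27_H_30_O_16_,[M-H],609.14,609.1461,0.01,False
3,Trifloroside,C_35_H_42_O_20_,[M-H],781.22,781.2197,0.0,False
4,4-beta-d-glu-trifloroside,C_41_H_52_O_25_,[M-H],943.27,943.2725,0.0,False
5,4''-O-beta-d-glucopyranosy1-6'-O-(4-O-beta-d-glucopyranosylcaffeoyl)linearroside,C_46_H_56_O_25_,[M-H],1007.3,1007.3038,0.0,False
6,Macrophylloside A,C_40_H_44_O_22_,[M-H],875.22,875.2251,0.01,False
7,Scabraside,C_40_H_44_O_20_,[M-H],843.24,843.2353,0.0,False
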