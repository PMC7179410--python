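species,location,sample_numbers
Gentiana scabra,QY-wdz,1-20
Gentiana scabra,QY--yem,21-39
Gentiana scabra,QY-,40-49
Gentiana scabra,Ys-y,50
Gentiana scabra,Ys-a,51
Gentiana scabra,Ys-j,52
Gentiana rigescens,Yx-hsc,53-57
Gentiana rigescens,Yx-jfc,58-62
Gentiana rigescens,Yx-xh,63-72
Gentiana rigescens,Yx-th,73-86
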