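pair_id,family,species,reproduction,d,optimum,breadth_pc1,breadth_pc1_sig,breadth_pc2,breadth_pc2_sig,scenario,annotation
1,Asteraceae,Ageratina adenophora,apomictic,0.234,s,c,0,b,0,B,E
1,Asteraceae,Mikania micrantha,sexual,0.1751,s,b,0,c,0,B,U
2,Asteraceae,Chromolaena odorata,apomictic,0.3531,ns,b,0,c,0,F,
2,Asteraceae,Eupatorium cannabinum,sexual,0.3121,s,b,0,b,1,C,E&U
3,Asteraceae,Erigeron annuus,apomictic,0.2199,s,c,1,c,1,A,U
3,Asteraceae,Erigeron canadensis,sexual,0.1926,s,c,1,c,1,A,U
4,Euphorbiaceae,Euphorbia esula,apomictic,0.2576,s,b,1,b,1,C,E
4,Euphorbiaceae,Euphorbia cyparissias,sexual,0.4368,s,b,1,b,1,C,E
5,Hypericaceae,Hypericum perforatum,apomictic,0.3459,s,b,1,b,1,C,E
5,Hypericaceae,Hypericum androsaemum,sexual,0.4275,s,b,0,b,1,C,
6,Melastomataceae,Clidemia hirta,apomictic,0.1959,s,b,0,c,1,A,U
6,Melastomataceae,Miconia calvescens,sexual,0.1948,ns,c,1,c,1,D,U
7,Poaceae,Brachiaria brizantha,apomictic,0.1398,s,b,0,b,0,B,E&U
7,Poaceae,Brachiaria ruziziensis,sexual,0.0423,s,b,1,b,0,C,E&U
8,Poaceae,Cortaderia jubata,apomictic,0.3368,s,c,1,c,0,A,U
8,Poaceae,Cortaderia selloana,sexual,0.3156,s,b,1,c,1,,E&U
9,Poaceae,Eragrostis curvula,apomictic,0.5107,s,b,1,b,0,C,
9,Poaceae,Eragrostis superba,sexual,0.2379,s,c,0,b,0,B,E&U
10,Poaceae,Paspalum conjugatum,apomictic,0.317,s,c,0,b,0,B,
10,Poaceae,Paspalum urvillei,sexual,0.3329,s,b,0,b,0,B,E
11,Poaceae,Poa pratensis,apomictic,0.3649,s,b,1,b,1,C,E
11,Poaceae,Poa annua,sexual,0.3208,s,b,1,b,1,C,E
12,Rosaceae,Potentilla recta,apomictic,0.3356,s,c,1,b,1,,U
12,Rosaceae,Duchesnea indica,sexual,0.3025,s,c,0,c,1,A,U
13,Rosaceae,Rubus pensilvanicus,apomictic,0.0026,s,c,0,b,0,B,E&U
13,Rosaceae,Rubus phoenicolasius,sexual,0.0336,s,b,1,b,1,C,E&U
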