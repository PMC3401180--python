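# nestkin fixture: inferred queen diploid genotypes, 20 solitary nests x 15 microsatellite loci (raw as published)
nest,At003,A088,AB124,AB024,Ag005a,Ap085,Ap226,A107,Ap049,Ap243,Ap273,Ad3,Ap036,Ap256,A14
1,218/218,150/150,250/250,92/92,110/110,200/200,229/229,204/204,150/150,260/260,110/110,167/167,160/160,206/206,230/230
2,218/220,150/150,250/250,92/92,112/112,200/200,229/229,198/198,142/142,254/260,110/120,157/157,168/168,214/214,214/230
3,218/218,150/150,254/254,100/100,112/112,198/198,233/233,198/198,150/150,254/260,120/120,157/157,160/160,214/214,214/214
4,218/220,150/150,254/254,100/100,112/112,198/198,229/233,204/204,152/152,254/254,120/120,167/167,160/160,214/214,230/230
5,218/218,150/150,254/254,100/100,110/110,200/200,233/233,198/198,150/150,254/260,120/120,157/157,168/168,206/206,230/230
6,218/218,154/154,254/254,100/100,110/110,198/198,233/233,204/204,150/150,260/260,110/110,157/157,160/160,206/214,214/214
7,200/200,154/154,244/244,104/104,100/110,210/210,229/243,206/216,150/160,254/270,114/114,169/175,168/180,200/210,2102/14
8,212/212,148/148,252/252,108/108,118/118,196/196,237/237,206/206,144/144,256/256,116/116,161/169,178/178,216/216,220/220
9,212/212,146/146,254/254,110/110,116/116,196/196,235/237,200/200,148/148,256/262,108/120,169/169,172/178,220/220,220/220
10,212/212,146/146,254/254,108/108,116/116,192/192,235/237,200/200,144/148,256/256,116/116,169/169,172/172,216/216,214/214
11,216/216,148/148,252/252,108/108,118/118,192/196,235/235,206/206,148/148,262/262,108/108,161/161,178/178,216/216,214/214
12,216/216,148/148,254/254,110/110,118/118,196/196,237/237,206/206,148/148,256/256,110/110,161/161,172/172,216/220,220/220
13,212/212,146/146,252/252,110/110,118/118,196/196,235/237,206/206,144/148,262/262,108/108,169/169,172/172,220/220,214/214
14,218/220,140/150,242/246,100/102,104/106,202/204,231/237,212/220,138/146,264/272,112/120,159/171,166/172,202/212,210/216
15,200/210,142/142,246/246,106/106,118/118,210/210,229/243,208/208,138/148,256/260,120/120,173/173,174/180,208/208,224/224
16,212/218,150/156,246/248,102/110,108/114,196/198,231/237,196/206,142/158,254/270,114/120,171/177,168/178,206/218,210/218
17,200/204,148/152,254/256,106/108,104/110,206/210,229/235,216/220,146/160,256/268,108/114,157/169,162/174,202/214,212/226
18,200/204,158/160,244/248,102/104,116/120,196/198,237/245,196/212,140/152,254/264,110/116,167/173,170/170,210/220,216/220
19,218/220,150/154,240/250,92/98,102/110,198/208,233/247,198/218,140/158,254/260,114/120,159/165,166/180,202/216,218/230
20,218/220,150/158,240/250,92/98,102/110,198/208,233/247,198/218,142/158,260/260,114/114,165/167,166/180,202/216,230/230
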