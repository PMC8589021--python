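marker,allele_size_range_bp,total_alleles,mean_alleles_per_individual,pic_cip,pic_usda,motif
IBS11,224-278,15,3.42,0.8113,0.8155505,(TTC)10
IBS141,123-157,17,4.06,0.8688,0.8375046,(CTTT)6
IBS199,168-218,26,4.00,0.8616,0.8530219,(ACA)7
IbJ116A,202-265,19,3.42,0.7933,0.7983935,(CCT)7
IBE2,106-166,20,2.98,0.8695,0.8453308,(TCT)13
IBS30,189-250,20,3.50,0.8114,0.7948903,(ATT)9
IBS82,138-163,15,3.50,0.8172,0.8128695,(TCA)7
IB286,105-134,10,3.2,0.8408,0.8139889,(CT)12
IBS28,180-246,24,3.6,0.8657,0.8278914,(TTC)8
IBC12,111-147,11,3.4,0.8028,0.8187527,(TTC)6
IBS139,301-354,27,2.89,0.8446,0.85462,(GA)7
IbY44,183-219,13,3.62,0.8023,0.8079592,(AGA)6
IBS44,127-130,12,3.69,0.8159,0.8068511,(ATC)8
IbJ10a,177-224,12,2.82,0.8123,0.8295309,(AAG)6
IbJ522a,223-268,9,2.59,0.6500,0.602318,(CAC)7
IBS14,188-212,5,2.64,0.5180,0.5073643,(TATG)7
IbJ1809,137-158,8,2.87,0.7264,0.734734,(CCT)6
IBY60,188-225,14,3.14,0.7782,0.7717795,(TAT)5
IBS24,145-181,12,2.89,0.7320,0.7230113,(CTGC)7
IbJ544b,191-211,8,2.34,0.6103,0.5771447,(TCT)5
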