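substance_atc,substance,indication,line,recommended_total_g,pack_totals_g,n_total,n_conform,pct_conform,n_under,pct_under,n_over,pct_over
J01XE01,nitrofurantoin,UTI,first,1,2; 3; 5,103.14,0.00,0.00,0.00,0.00,103.14,100.00
J01EE01,sulfamethoxazole/trimethoprim,UTI,first,5.76,9.6; 19.2; 48,74.49,0.00,0.00,0.00,0.00,74.49,100.00
J01XX01,fosfomycin,UTI,second,3,3,97.21,97.21,100.00,0.00,0.00,0.00,0.00
J01MA06,norfloxacin,UTI,second,2.4,2.4; 5.6; 16.8,4.36,0.00,0.00,0.00,0.00,4.36,100.00
J01DC02,cefuroxime,UTI,second,3,3.5; 7,50.28,0.00,0.00,0.00,0.00,50.28,100.00
J01CR02,amoxicillin/clavulanic acid,UTI,second,4.5,6.25; 12; 12.5; 20,264.11,0.00,0.00,0.00,0.00,264.11,100.00
J01CA04,amoxicillin,ABRS,first,10 to 21,3; 6; 10; 14; 15; 20,116.69,84.39,72.32,32.30,27.68,0.00,0.00
J01CR02,amoxicillin/clavulanic acid,ABRS,first,10 to 14,6.25; 12; 12.5; 20,264.11,116.66,44.17,65.53,24.81,81.92,31.02
J01DC02,cefuroxime,ABRS,second,5 to 7,3.5; 7,50.28,35.86,71.32,14.42,28.68,0.00,0.00
J01AA02,doxycycline,ABRS,second,1 to 1.4,0.8; 1; 1.12; 1.4; 1.6; 2; 2.24; 2.5; 3.2,35.87,15.19,42.34,6.83,19.05,13.85,38.61
J01FA09,clarithromycin,ABRS,second,5,3.5; 5; 7; 10; 15,36.83,9.60,26.08,7.50,20.37,19.72,53.56
J01CA04,amoxicillin,CAP,first,15,3; 6; 10; 14; 15; 20,116.69,19.94,17.09,72.58,62.20,24.17,20.71
J01CR02,amoxicillin/clavulanic acid,CAP,first,15,6.25; 12; 12.5; 20,264.11,0.00,0.00,182.19,68.98,81.92,31.02
J01AA02,doxycycline,CAP,second,1,0.8; 1; 1.12; 1.4; 1.6; 2; 2.24; 2.5; 3.2,35.87,4.55,12.67,6.83,19.05,24.49,68.28
J01FA10,azithromycin,CAP,second,1.5,0.3; 0.9; 1; 1.5,13.75,0.00,0.00,13.75,100.00,0.00,0.00
J01EE01,sulfamethoxazole/trimethoprim,CAP,second,9.6,9.6; 19.2; 48,74.49,16.89,22.67,0.00,0.00,57.60,77.33
J01CA04,amoxicillin,OM,first,15,3; 6; 10; 14; 15; 20,116.69,19.94,17.09,72.58,62.20,24.17,20.71
J01CR02,amoxicillin/clavulanic acid,OM,second,15,6.25; 12; 12.5; 20,264.11,0.00,0.00,182.19,68.98,81.92,31.02
J01DC02,cefuroxime,OM,second,5,3.5; 7,50.28,0.00,0.00,14.42,28.68,35.86,71.32
J01CE02,penicillin V,SP,first,7.5,7.5; 11.25; 15; 22.5,13.57,4.47,32.97,0.00,0.00,9.10,67.03
J01CA04,amoxicillin,SP,first,12,3; 6; 10; 14; 15; 20,116.69,0.00,0.00,68.07,58.33,48.62,41.67
J01DC02,cefuroxime,SP,second,6,3.5; 7,50.28,0.00,0.00,14.42,28.68,35.86,71.32
J01FA09,clarithromycin,SP,second,6,3.5; 5; 7; 10; 15,36.83,0.00,0.00,17.10,46.44,19.72,53.56
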