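id,formula,n_deuterium,polarity,expected_rt,primary_adduct,primary_n_deuterium,primary_printed_mz,products,printed_mz
IS_Car_4:0-d7,C11H21NO4,7,+ve,0.3,[M+H]+,7,239.1983,[M+H]+@7,239.1983
IS_LPC_14:0-d42,C19H42NO4P,42,+ve,0.4,[M+H]+,42,422.5560,[M+H]+@42; [M+H]+@41; [M+H]+@40,422.5560; 421.5498; 420.5435
IS_Car_16:0-d3,C23H45NO4,3,+ve,0.5,[M+H]+,3,403.3610,[M+H]+@3,403.3610
IS_FA_17:0-d33,C17H34O2,33,-ve,1.1,[M-H]-,33,302.4557,[M-H]-@33; [M-H]-@32; [M-H]-@31,302.4557; 301.4495; 300.4432
IS_PS_28:0-d54,C34H66NO10P,54,-ve,1.4,[M-H]-,54,732.7741,[M-H]-@54; [M-H]-@53; [M-H]-@52; [M-H]-@51; [M-H]-@50,732.7741; 731.7678; 730.7615; 729.7553; 728.7490
IS_PI_34:1-d31,C43H81O13P,31,-ve,2.9,[M-H]-,31,866.7288,[M-H]-@29; [M-H]-@30; [M-H]-@31,864.7162; 865.7225; 866.7288
IS_SM_34:1-d31,C39H79N2O6P,31,+ve,3.0,[M+H]+,30,733.7632,[M+H]+@30; [M+H]+@31; [M+Na]+@30; [M+Na]+@31; [M+K]+@30; [M+K]+@31,733.7632; 734.7670; 755.7451; 756.7514; 771.7190; 772.7253
IS_PG_34:1-d31,C40H77O10P,31,-ve,3.0,[M-H]-,31,778.7127,[M-H]-@28; [M-H]-@29; [M-H]-@30; [M-H]-@31,775.6939; 776.7002; 777.7065; 778.7127
IS_PA_34:1-d31,C37H71O8P,31,-ve,3.4,[M-H]-,31,704.6760,[M-H]-@27; [M-H]-@28; [M-H]-@29; [M-H]-@30; [M-H]-@31,700.6509; 701.6571; 702.6634; 703.6697; 704.6760
IS_Cer_16:0-d31,C34H67NO3,31,+ve,3.9,[M+H]+,31,569.7139,[M+H-H2O]+@28; [M+H-H2O]+@29; [M+H-H2O]+@30; [M+H-H2O]+@31; [M+H]+@28; [M+H]+@29; [M+H]+@30; [M+H]+@31; [M+Na]+@30; [M+Na]+@31; [M+K]+@30; [M+K]+@31,548.6851; 549.6914; 550.6977; 551.7039; 566.6951; 567.7014; 568.7076; 569.7139; 590.6896; 591.6959; 606.6636; 607.6698
IS_PC_34:1-d31,C42H82NO8P,31,+ve,3.9,[M+Na]+,31,813.7616,[M+H]+@30; [M+H]+@31; [M+Na]+@30; [M+Na]+@31; [M+K]+@30; [M+K]+@31,790.7700; 791.7750; 812.7553; 813.7616; 828.7292; 829.7355
IS_PE_34:1-d31,C39H76NO8P,31,+ve,4.0,[M+H]+,31,749.7327,[M+H]+@29; [M+H]+@30; [M+H]+@31; [M+Na]+@29; [M+Na]+@30; [M+Na]+@31; [M+K]+@29; [M+K]+@30; [M+K]+@31,747.7181; 748.7254; 749.7327; 769.7021; 770.7084; 771.7146; 785.6760; 786.6823; 787.6886
IS_TG_45:0-d87,C48H92O6,87,+ve,5.8,[M+H]+,87,853.2427,[M+H]+@84; [M+H]+@85; [M+H]+@86; [M+H]+@87; [M+NH4]+@84; [M+NH4]+@85; [M+NH4]+@86; [M+NH4]+@87; [M+Na]+@84; [M+Na]+@85; [M+Na]+@86; [M+Na]+@87; [M+K]+@84; [M+K]+@85; [M+K]+@86; [M+K]+@87,850.2239; 851.2301; 852.2364; 853.2427; 867.2504; 868.2567; 869.2630; 870.2693; 872.2059; 873.2121; 874.2184; 875.2247; 888.1798; 889.1861; 890.1923; 891.1986
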