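class_code,class_name,n_species,adducts,internal_standard,ionisation_mode
Carn,Acyl-carnitines,48,[M+H]+,IS_Car_4:0-d7; IS_Car_16:0-d3,+ve
Cer,Ceramides,85,[M+H]+; [M+H-H2O]+,IS_Cer_16:0-d31,+ve
CL,Cardiolipins,56,[M-H]-,IS_TG_45:0-d87,-ve
DG,Diacylglycerols,6,[M+H-H2O]+; [M+Na]+; [M+K]+,IS_TG_45:0-d87,+ve
GM1,Gangliosides (GM1),24,[M-H]-,IS_PG_34:1-d31,-ve
Hex-Cer,Hexosylceramides,56,[M+H]+; [M+H-H2O]+,IS_Cer_16:0-d31,+ve
LPC,Lyso-phosphatidylcholines,23,[M+H]+,IS_LPC_14:0-d42,+ve
LPE,Lyso-phosphatidylethanolamines,19,[M+H]+,IS_LPC_14:0-d42,+ve
LPI,Lyso-phosphatidylinositols,19,[M-H]-,IS_PI_34:1-d31,-ve
LPS,Lyso-phosphoserines,20,[M-H]-,IS_PS_28:0-d54,-ve
Lyso_CL,Lyso-cardiolipins,23,[M-H]-,IS_TG_45:0-d87,-ve
MG,Monoacylglycerols,1,[M+H-H2O]+; [M+Na]+; [M+K]+,IS_TG_45:0-d87,+ve
PA,Phosphatidic acids,26,[M-H]-,IS_PA_34:1-d31,-ve
PC,Phosphatidylcholines,43,[M+H]+,IS_PC_34:1-d31,+ve
PE,Phosphatidylethanolamines,19,[M+H]+,IS_PE_34:1-d31,+ve
PG,Phosphatidylglycerol,34,[M-H]-,IS_PG_34:1-d31,-ve
PI,Phosphatidylinositols,21,[M-H]-,IS_PI_34:1-d31,-ve
PS,Phosphatidylserines,36,[M-H]-,IS_PS_28:0-d54,-ve
S,Sulfatides,72,[M-H]-,IS_PG_34:1-d31,-ve
SM,Sphingomyelins,54,[M+H]+; [M+Na]+; [M+K]+,IS_SM_34:1-d31,+ve
TG,Triacylglycerides,89,[M+H]+; [M+NH4]+; [M+Na]+; [M+K]+,IS_TG_45:0-d87,+ve
FA,Fatty acids,,[M-H]-,IS_FA_17:0-d33,-ve
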