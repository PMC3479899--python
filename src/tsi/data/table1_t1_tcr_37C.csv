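# Kinetic binding parameters for the T1 TCR recognizing the ligand panel
# 4P (negatively selecting), 4A (threshold), 4N (positively selecting),
# measured on single-positive (SP) and double-positive (DP) thymocytes at 37 C.
# Values are stored exactly as printed in the source data summary.
cell_type,ligand,temperature_C,Kd_M,t_half_s,kon_per_M_s,kplus_per_s,kminus_per_s
SP thymocyte,4P,37,1.1e-7,41,153691,5.1230e-10,0.0169
SP thymocyte,4A,37,5.5e-6,0.8,157533,5.2511e-10,0.8664
SP thymocyte,4N,37,5.8e-5,0.08,149385,4.9795e-10,8.6643
DP thymocyte,4P,37,8.8e-8,39,201966,6.7322e-10,0.01778
DP thymocyte,4A,37,2.2e-6,0.79,398161,1.3272e-9,0.8760
DP thymocyte,4N,37,2.9e-5,0.23,105719,3.5240e-10,3.0658
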