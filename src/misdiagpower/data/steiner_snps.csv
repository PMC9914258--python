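label,gene,theta0,delta_t,ci_low,ci_high,p_value,significant_in_original,n0,n1,pi_se,pi_sp,copies_per_subject
rs3087243,CTLA4,0.56,1.54,1.17,2.03,0.002,True,201,305,1.0,1.0,2
rs2476601,PTPN22,0.08,1.63,1.04,2.55,0.033,True,201,305,1.0,1.0,2
rs1799724,TNF,0.13,0.84,0.56,1.27,0.409,False,201,305,1.0,1.0,2
rs1800629,TNF,0.16,0.89,0.61,1.30,0.551,False,201,305,1.0,1.0,2
rs3807306,IRF5,0.51,0.94,0.72,1.22,0.637,False,201,305,1.0,1.0,2
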