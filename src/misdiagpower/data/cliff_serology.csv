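label,gene,theta0,delta_t,ci_low,ci_high,p_value,significant_in_original,n0,n1,pi_se,pi_sp,copies_per_subject
HSV1,,0.42,1.60,0.83,3.09,0.163,False,107,251,0.975,0.975,1
HSV2,,0.34,1.36,0.69,2.66,0.377,False,107,251,0.975,0.975,1
EBV,,0.93,0.65,0.21,1.97,0.442,False,107,251,0.975,0.975,1
CMV,,0.37,0.84,0.42,1.67,0.613,False,107,251,0.975,0.975,1
VZV,,0.97,0.75,0.12,4.63,0.757,False,107,251,0.975,0.975,1
HHV6,,0.95,1.27,0.24,6.79,0.776,False,107,251,0.975,0.975,1
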