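start,end,class,n_patients
1,160,breast,16
161,310,cervical,21
311,352,leukemia,7
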