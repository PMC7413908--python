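analyte,e1_mean_ng_l,e2_mean_ng_l,e1_censored,e2_censored
atenolol,6211.7,5925.0,False,False
bisoprolol,808.3,1003.3,False,False
metoprolol,65.0,,False,True
mirtazapine,621.7,295.0,False,False
oxazepam,396.7,555.0,False,False
propranolol,916.7,1436.7,False,False
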