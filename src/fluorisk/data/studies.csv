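study_id,location,tea_type,n_brands,n_samples,year,mean_mgL,min_mgL,max_mgL,sd_mgL,eval_conc_mgL
23,Tehran-Iran,Tea Bag,15,,2008,0.26,0.13,0.44,0.01,0.36
26,Tehran-Iran,Tea Bag,6,36,2010,2.02,0.7,3.27,1.06,2.63
27,Qom-Iran,Tea Bag,4,,2012,1.28,1.11,1.44,,1.36
28,Tehran-Iran,Tea Bag,10,,2006,1.63,0.53,2.6,0.16,2.09
17,Hamadan-Iran,Tea Bag,22,,2012,1.139,0.48,2.3,,1.8
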