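il_id,name,log_inv_ec50_exp,C-0.008,C-0.004,C-0.003,C0.002,C0.003,C0.005,C0.009,C0.014,A-0.006,A-0.001,A0.004,log_inv_ec50_pred
NEW-1,1-(ethoxymethyl)-3-methylimidazolium chloride,-2.61,13.681,15.909,11.369,4.648,1.598,0.548,1.053,0.987,0,0,0,-2.49
NEW-2,4-(dimethylamino)-1-butylpyridinium bis(trifluoromethylsulfonyl)amide,-0.59,14.142,24.318,29.208,8.783,5.369,0.038,0,0,0.438,7.713,8.108,-0.67
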