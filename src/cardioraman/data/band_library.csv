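name,center,window,fwhm,species,unique
nu_604,604,8,14,cyt_c_red,1
nu_750,750,8,14,cyt_c_red,0
nu_1127,1127,8,14,cyt_b_red,0
nu_1300,1300,8,14,cyt_b_red,0
nu_1310,1310,8,14,cyt_c_red,0
nu_1337,1337,8,14,cyt_b_red,1
nu4_dMb_1358,1358,8,14,dMb,1
nu4_oMb_1377,1377,8,14,oMb,1
nu_1556,1556,8,14,dMb,0
nu_1582,1582,8,14,cyt_c_red,0
nu_1587,1587,8,14,oMb,0
nu_1606,1606,8,14,dMb,0
nu_1640,1640,8,14,oMb,0
amide_I_1658,1658,8,40,amide_I,0
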