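code,label,level,mean,lower,upper
HC1,Curative care,1,523,338,604
HC1.1,Curative care - inpatient,2,223,155,276
HC1.2,Curative care - day,2,20,10,36
HC1.3,Curative care - outpatient,2,232,137,291
HC1.4,Curative care - home-based,2,6,4,12
HC1.nec,Curative care - NEC,2,42,14,92
HC2,Rehabilitative care,1,25,12,74
HC2.1,Rehabilitative care - inpatient,2,11,5,31
HC2.2,Rehabilitative care - day,2,2,1,5
HC2.3,Rehabilitative care - outpatient,2,6,2,20
HC2.4,Rehabilitative care - home-based,2,1,0,5
HC2.nec,Rehabilitative care - NEC,2,5,1,19
HC3,Long-term care,1,76,55,117
HC3.1,Long-term care - inpatient,2,49,29,77
HC3.2,Long-term care - day,2,4,2,7
HC3.3,Long-term care - outpatient,2,1,0,3
HC3.4,Long-term care - home-based,2,14,8,23
HC3.nec,Long-term care - NEC,2,8,1,26
HC4,Ancillary care,1,59,23,149
HC5,Medical goods,1,178,132,274
HC5.1,Medical goods - pharms and other medical non-durable goods,2,136,92,214
HC5.2,Medical goods - therapeutic appliances and prosthetics,2,24,15,42
HC5.nec,Medical goods - NEC,2,18,5,47
HC6,Preventative care,1,47,33,72
HC6.1,Prevention care - IEC programmes,2,5,3,9
HC6.2,Prevention care - immunisation programmes,2,4,2,8
HC6.3,Prevention care - early disease detection,2,2,1,4
HC6.4,Prevention care - healthy condition monitoring programmes,2,7,4,14
HC6.5,Prevention care - EPI surveillance and risk and disease control programmes,2,4,3,7
HC6.6,Prevention care - preparing for disaster and emergency response programmes,2,1,0,2
HC6.nec,Prevention care - NEC,2,23,14,37
HC7,Governance and admin,1,64,40,110
HC9,Other healthcare services,1,47,25,83
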