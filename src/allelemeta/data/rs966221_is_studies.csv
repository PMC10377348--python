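study_id,region,n_cases,n_controls,case_CC,case_CT,case_TT,control_CC,control_CT,control_TT,hwe_p_reported
Zhang 2019,Central,881,892,86,341,454,43,282,567,0.308
Jiang 2018,South,101,104,1,30,70,4,22,78,0.228
Wang 2017,Central,610,618,312,240,58,410,182,24,0.501
Luo 2014,South,712,774,21,207,484,18,203,553,0.893
Shao 2013,East,394,382,12,123,159,21,120,241,0.287
Wang 2012,East,235,105,16,82,137,4,25,76,0.450
Cheng 2011,East,280,258,12,102,166,12,94,125,0.312
Sun 2009,East,649,761,40,223,385,35,230,496,0.254
Xue 2009,Multi,424,887,27,144,253,29,255,603,0.813
Zhang 2009,Northeast,122,44,7,46,69,4,10,30,0.067
Xu 2008,East,116,110,4,46,66,6,29,75,0.201
Wang 2015,North,396,300,13,123,260,19,100,181,0.324
Li 2010,Northeast,371,371,117,173,81,76,197,98,0.208
Zhao 2012,Northeast,682,598,210,320,152,138,310,150,0.366
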