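stage,parameter,mean,sd,n
P2-P3,isi_avg,1.06,0.84,9
P2-P3,cv_isi,130.5,40.1,9
P2-P3,tau_m,200.3,8.0,5
P2-P3,r_in,1642,420,5
P2-P3,c_m,129,34,5
P2-P3,sag,28.2,4.0,9
P2-P3,rebound,465,134,6
P2-P3,ap_threshold,-43.9,3.3,9
P2-P3,ap_amplitude,59.5,9.6,9
P2-P3,ap_half_width,2.38,0.62,9
P2-P3,ap_rise_slope,47.6,21.7,9
P2-P3,ap_decay_slope,-19.6,5.2,9
P2-P3,ahp,14.1,4.9,9
P2-P3,gain_start,32.1,5.9,6
P2-P3,gain_end,20,7.8,6
P2-P3,sfa_index,1.76,0.53,6
P5,isi_avg,1.36,1.60,15
P5,cv_isi,57.6,22.6,15
P5,tau_m,86.9,13.7,11
P5,r_in,642,163,11
P5,c_m,146,52,11
P5,sag,29.4,5.7,14
P5,rebound,339,188,12
P5,ap_threshold,-40.3,4.5,15
P5,ap_amplitude,47.1,7.4,15
P5,ap_half_width,2.99,0.95,15
P5,ap_rise_slope,24.5,10.8,15
P5,ap_decay_slope,-16.9,4.6,15
P5,ahp,20.1,4.5,15
P5,gain_start,17.7,5,7
P5,gain_end,8.8,2.1,7
P5,sfa_index,2.07,0.71,7
P6,isi_avg,0.78,0.56,18
P6,cv_isi,51.5,43.0,18
P6,tau_m,70.3,23.9,18
P6,r_in,612,170,18
P6,c_m,118,32,18
P6,sag,30.2,7.2,18
P6,rebound,316,127,18
P6,ap_threshold,-43.1,4.3,19
P6,ap_amplitude,49.0,9.2,19
P6,ap_half_width,2.99,0.71,19
P6,ap_rise_slope,25.1,19.2,19
P6,ap_decay_slope,-18.0,6.6,19
P6,ahp,21.0,3.7,19
P6,gain_start,22.7,6.5,10
P6,gain_end,11.7,3.7,10
P6,sfa_index,1.97,0.27,10
P7,isi_avg,0.97,0.93,36
P7,cv_isi,38.4,28.0,36
P7,tau_m,89.3,24.4,25
P7,r_in,650,174,26
P7,c_m,143,38,25
P7,sag,31.2,5.2,25
P7,rebound,249,89,19
P7,ap_threshold,-39.8,4.0,35
P7,ap_amplitude,46.3,7.8,35
P7,ap_half_width,2.92,0.64,35
P7,ap_rise_slope,23.8,8.6,35
P7,ap_decay_slope,-17.6,4.1,35
P7,ahp,22.6,3.7,35
P7,gain_start,17.5,4.7,13
P7,gain_end,8.83,2.4,13
P7,sfa_index,2.08,0.71,13
P8-P9,isi_avg,1.67,1.95,18
P8-P9,cv_isi,38.0,23.2,18
P8-P9,tau_m,90.9,38.4,21
P8-P9,r_in,576,268,21
P8-P9,c_m,200,141,21
P8-P9,sag,29.6,6.2,17
P8-P9,rebound,401,212,15
P8-P9,ap_threshold,-42.8,4.3,20
P8-P9,ap_amplitude,54.4,7.4,20
P8-P9,ap_half_width,2.74,0.82,20
P8-P9,ap_rise_slope,32.8,14.8,20
P8-P9,ap_decay_slope,-20.2,5.9,20
P8-P9,ahp,20.9,4.2,20
P8-P9,gain_start,18.1,4.3,13
P8-P9,gain_end,10.4,3.3,13
P8-P9,sfa_index,1.80,0.31,13
P10-P11,isi_avg,0.68,0.41,12
P10-P11,cv_isi,21.1,8.6,12
P10-P11,tau_m,80.6,28.6,10
P10-P11,r_in,327,210,10
P10-P11,c_m,281,109,10
P10-P11,sag,33.3,4.2,10
P10-P11,rebound,330,165,10
P10-P11,ap_threshold,-41.7,4.2,11
P10-P11,ap_amplitude,50.6,11.6,11
P10-P11,ap_half_width,2.51,0.83,11
P10-P11,ap_rise_slope,36.3,21.2,11
P10-P11,ap_decay_slope,-21.4,7.5,11
P10-P11,ahp,20.7,4.9,11
P10-P11,gain_start,11,4.5,10
P10-P11,gain_end,11.5,5.3,10
P10-P11,sfa_index,1.01,0.30,10
P12-P13,isi_avg,1.04,0.67,15
P12-P13,cv_isi,19.6,15.1,15
P12-P13,tau_m,87.9,32.7,17
P12-P13,r_in,369,166,17
P12-P13,c_m,297,226,17
P12-P13,sag,32.4,3.7,16
P12-P13,rebound,378,341,16
P12-P13,ap_threshold,-45.4,3.7,18
P12-P13,ap_amplitude,62.1,6.3,18
P12-P13,ap_half_width,1.86,0.27,18
P12-P13,ap_rise_slope,54.2,14.5,18
P12-P13,ap_decay_slope,-29.7,4.2,18
P12-P13,ahp,23.0,6.0,18
P12-P13,gain_start,13.2,5,15
P12-P13,gain_end,11.6,4.5,15
P12-P13,sfa_index,1.29,0.80,15
P14,isi_avg,0.64,0.48,16
P14,cv_isi,12.8,8.3,16
P14,tau_m,92.3,44.0,14
P14,r_in,460,192,14
P14,c_m,205,68,14
P14,sag,35.6,2.9,10
P14,rebound,489,448,9
P14,ap_threshold,-44.2,2.3,16
P14,ap_amplitude,61.0,7.1,16
P14,ap_half_width,1.91,0.54,16
P14,ap_rise_slope,54.9,18.4,16
P14,ap_decay_slope,-30.9,8.5,16
P14,ahp,24.1,5.5,16
P14,gain_start,12.2,4,10
P14,gain_end,9.8,2.6,10
P14,sfa_index,1.30,0.50,10
P15-P16,isi_avg,0.88,0.38,22
P15-P16,cv_isi,13.3,6.6,22
P15-P16,tau_m,77.8,28.5,19
P15-P16,r_in,325,117,19
P15-P16,c_m,245,67,19
P15-P16,sag,27.9,6.5,33
P15-P16,rebound,340,207,30
P15-P16,ap_threshold,-44.4,3.4,30
P15-P16,ap_amplitude,60.1,6.5,30
P15-P16,ap_half_width,1.63,0.49,30
P15-P16,ap_rise_slope,56.2,18.3,30
P15-P16,ap_decay_slope,-39.7,11.5,30
P15-P16,ahp,26.1,4.0,30
P15-P16,gain_start,9.28,3.2,26
P15-P16,gain_end,9.28,4.2,26
P15-P16,sfa_index,1.11,0.44,26
P17,isi_avg,0.82,0.40,16
P17,cv_isi,9.9,5.6,16
P17,tau_m,83.5,25.7,20
P17,r_in,323,109,22
P17,c_m,283,160,20
P17,sag,28.1,7.4,35
P17,rebound,375,270,26
P17,ap_threshold,-44.6,3.5,28
P17,ap_amplitude,62.1,8.6,28
P17,ap_half_width,1.61,0.37,28
P17,ap_rise_slope,58.2,16.2,28
P17,ap_decay_slope,-38.8,8.8,28
P17,ahp,28.1,5.0,28
P17,gain_start,7.13,2.1,14
P17,gain_end,8.28,2.9,14
P17,sfa_index,0.92,0.31,14
P18,isi_avg,0.63,0.30,18
P18,cv_isi,7.6,4.0,18
P18,tau_m,89.0,24.2,18
P18,r_in,340,118,18
P18,c_m,280,86,18
P18,sag,29.5,4.2,22
P18,rebound,433,222,20
P18,ap_threshold,-41.6,3.0,21
P18,ap_amplitude,55.5,4.7,21
P18,ap_half_width,1.45,0.21,21
P18,ap_rise_slope,50.6,15.6,21
P18,ap_decay_slope,-41.1,7.3,21
P18,ahp,28.4,3.2,21
P18,gain_start,6.97,2,12
P18,gain_end,7.59,2.9,12
P18,sfa_index,0.99,0.35,12
P19,isi_avg,0.71,0.32,24
P19,cv_isi,9.6,6.1,24
P19,tau_m,89.9,28.1,30
P19,r_in,352,103,30
P19,c_m,270,106,30
P19,sag,28.6,6.2,38
P19,rebound,456,278,32
P19,ap_threshold,-44.2,4.1,33
P19,ap_amplitude,58.2,8.8,33
P19,ap_half_width,1.55,0.38,33
P19,ap_rise_slope,54.3,21.1,33
P19,ap_decay_slope,-41.4,11.4,33
P19,ahp,27.4,4.6,33
P19,gain_start,8.32,2.6,19
P19,gain_end,9.3,2.6,19
P19,sfa_index,0.93,0.31,19
P20,isi_avg,0.77,0.42,21
P20,cv_isi,9.3,4.8,21
P20,tau_m,88.5,41.8,22
P20,r_in,375,116,23
P20,c_m,231,66,22
P20,sag,28.5,8.3,24
P20,rebound,572,493,22
P20,ap_threshold,-44.3,4.4,24
P20,ap_amplitude,61.6,8.8,24
P20,ap_half_width,1.47,0.31,24
P20,ap_rise_slope,59.3,21.2,24
P20,ap_decay_slope,-42.6,8.8,24
P20,ahp,28.0,5.0,24
P20,gain_start,8.15,2.4,16
P20,gain_end,9.21,3,16
P20,sfa_index,0.95,0.33,16
P21-P23,isi_avg,0.72,0.32,19
P21-P23,cv_isi,7.5,4.5,19
P21-P23,tau_m,93.1,48.2,21
P21-P23,r_in,319,115,23
P21-P23,c_m,293,128,21
P21-P23,sag,27.5,6.6,23
P21-P23,rebound,388,254,22
P21-P23,ap_threshold,-43.9,4.0,24
P21-P23,ap_amplitude,62.6,8.2,24
P21-P23,ap_half_width,1.50,0.37,24
P21-P23,ap_rise_slope,61.5,21.0,24
P21-P23,ap_decay_slope,-44.1,11.4,24
P21-P23,ahp,29.1,4.3,24
P21-P23,gain_start,6.79,2.1,24
P21-P23,gain_end,7,1.8,24
P21-P23,sfa_index,1.01,0.32,24
P28-P29,isi_avg,0.92,0.54,12
P28-P29,cv_isi,12.1,4.7,12
P28-P29,tau_m,148.3,42.6,10
P28-P29,r_in,472,88,10
P28-P29,c_m,316,83,10
P28-P29,sag,34.1,4.5,13
P28-P29,rebound,736,375,10
P28-P29,ap_threshold,-42.8,3.0,12
P28-P29,ap_amplitude,62.4,5.3,12
P28-P29,ap_half_width,1.49,0.29,12
P28-P29,ap_rise_slope,63.0,14.3,12
P28-P29,ap_decay_slope,-43.2,8.7,12
P28-P29,ahp,28.6,6.2,12
P28-P29,gain_start,6.99,2.3,10
P28-P29,gain_end,6.82,1.4,10
P28-P29,sfa_index,1.07,0.43,10
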