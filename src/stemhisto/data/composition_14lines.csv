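line_id,cell_wall_pct_dm,klason_lignin_pct_cw,ester_pca_pct_cw,ester_fa_pct_cw,ivcwd_pct
M01,52.7,20.51,1.59,0.62,32.7
M02,56.8,20.65,1.61,0.55,34.7
M03,55.5,18.24,1.68,0.72,37.8
M04,57.0,20.13,1.06,0.57,29.9
M05,52.0,15.88,1.29,0.64,41.0
M06,50.0,15.51,1.33,0.67,43.9
M07,62.0,16.58,1.81,0.58,39.0
M08,53.7,17.92,1.56,0.59,32.8
M09,63.6,17.10,1.38,0.64,32.7
M10,53.6,16.93,1.65,0.61,30.7
M11,47.6,20.40,1.94,0.57,27.6
M12,49.9,19.26,1.68,0.50,30.5
M13,61.8,19.15,1.89,0.66,25.4
M14,52.3,17.94,1.91,0.68,31.1
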