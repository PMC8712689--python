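line_id,region,mean_size_um,sd_size_um
M01,parenchyma_middle,70.0,27.9
M04,parenchyma_middle,81.8,31.6
M09,parenchyma_middle,65.5,29.1
M14,parenchyma_middle,64.2,29.4
M01,parenchyma_near_rind,57.9,31.6
M04,parenchyma_near_rind,54.9,30.6
M09,parenchyma_near_rind,46.0,27.4
M14,parenchyma_near_rind,56.2,34.9
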