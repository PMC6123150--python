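name,group,percent,included
Scan time,film scanner,0.2,True
Reproducibility of response,film scanner,0.2,True
Homogeneity,film scanner,0.4,True
Positioning,film scanner,0.1,True
Film reproducibility of response,film,0.3,True
Film homogeneity,film,0.2,True
Film uniformity,film,0.4,True
Film calibration curve fitting,film,7.8,True
Film positioning,film,5.6,True
Film orientation,film,7.5,False
Output,source,2.0,True
Energy spectrum,source,3.8,True
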