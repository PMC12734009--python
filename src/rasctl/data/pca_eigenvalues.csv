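component,eigenvalue,variance_pct,cumulative_pct
F1,2.452,49.045,49.045
F2,1.425,28.495,77.540
F3,0.497,9.930,87.470
F4,0.333,6.669,94.140
F5,0.293,5.860,100.000
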