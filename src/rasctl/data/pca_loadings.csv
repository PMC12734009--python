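indicator,label,F1,F2
X1,LZM activity,-0.089,-0.513
X2,SOD activity,0.480,0.285
X3,CAT activity,0.378,-0.060
X4,Cortisol level,0.050,0.488
X5,MDA content,-0.351,0.128
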