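behavior,ap,precision,recall,f1
Floating head behavior,98.40,98.60,95.20,96.87
Floating behavior,98.40,98.90,96.00,97.43
Rollover behavior,97.90,97.10,94.70,95.88
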