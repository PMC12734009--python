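plan,ambient_T,current_DO,target_T,target_DO,cost_exp,cost_ctl,profit_exp,profit_ctl
1,14,5,14,5,0.00,33.97,131.36,149.02
2,14,5,15,5,4.81,33.97,140.94,149.02
3,14,5,16,5,9.91,33.97,147.90,149.02
4,14,5,17,5,15.35,33.97,152.23,149.02
5,14,5,18,5,21.14,33.97,153.88,149.02
6,14,5,19,5,27.34,33.97,152.83,149.02
7,14,5,20,5,33.97,33.97,149.02,149.02
8,14,5,21,5,41.09,33.97,142.40,149.02
9,14,5,22,5,48.76,33.97,132.93,149.02
10,14,5,23,5,57.03,33.97,120.54,149.02
11,14,5,24,5,65.99,33.97,105.15,149.02
12,14,5,25,5,75.73,33.97,86.67,149.02
13,14,5,26,5,86.34,33.97,65.00,149.02
14,14,5,27,5,97.96,33.97,40.01,149.02
15,14,5,28,5,110.73,33.97,11.56,149.02
16,14,5,29,5,124.84,33.97,-20.54,149.02
17,14,5,30,5,140.50,33.97,-56.51,149.02
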