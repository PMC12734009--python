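plan,ambient_T,current_DO,target_T,target_DO,cost_exp,cost_ctl,profit_exp,profit_ctl
1,8,5,10,5,9.91,86.34,40.76,96.64
2,8,5,11,5,15.35,86.34,58.96,96.64
3,8,5,12,5,21.14,86.34,74.50,96.64
4,8,5,13,5,27.34,86.34,87.32,96.64
5,8,5,14,5,33.97,86.34,97.39,96.64
6,8,5,15,5,41.09,86.34,104.65,96.64
7,8,5,16,5,48.76,86.34,109.06,96.64
8,8,5,17,5,57.03,86.34,110.55,96.64
9,8,5,18,5,65.99,86.34,109.04,96.64
10,8,5,19,5,75.73,86.34,104.44,96.64
11,8,5,20,5,86.34,86.34,96.64,96.64
12,8,5,21,5,97.96,86.34,85.53,96.64
13,8,5,22,5,110.73,86.34,70.96,96.64
14,8,5,23,5,124.84,86.34,52.74,96.64
15,8,5,24,5,140.50,86.34,30.65,96.64
16,8,5,25,5,157.98,86.34,4.42,96.64
17,8,5,26,5,177.63,86.34,-26.29,96.64
18,8,5,27,5,199.88,86.34,-61.91,96.64
19,8,5,28,5,225.27,86.34,-102.98,96.64
20,8,5,29,5,254.52,86.34,-150.23,96.64
21,8,5,30,5,288.59,86.34,-204.61,96.64
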