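plan,ambient_T,current_DO,target_T,target_DO,cost_exp,cost_ctl,profit_exp,profit_ctl
1,2,5,10,5,48.76,177.63,1.92,5.35
2,2,5,11,5,57.03,177.63,17.28,5.35
3,2,5,12,5,65.99,177.63,29.65,5.35
4,2,5,13,5,75.73,177.63,38.93,5.35
5,2,5,14,5,86.34,177.63,45.01,5.35
6,2,5,15,5,97.96,177.63,47.78,5.35
7,2,5,16,5,110.73,177.63,47.09,5.35
8,2,5,17,5,124.84,177.63,42.74,5.35
9,2,5,18,5,140.50,177.63,34.53,5.35
10,2,5,19,5,157.98,177.63,22.18,5.35
11,2,5,20,5,177.63,177.63,5.35,5.35
12,2,5,21,5,199.88,177.63,-16.39,5.35
13,2,5,22,5,225.27,177.63,-43.58,5.35
14,2,5,23,5,254.52,177.63,-76.95,5.35
15,2,5,24,5,288.59,177.63,-117.45,5.35
16,2,5,25,5,328.78,177.63,-166.38,5.35
17,2,5,26,5,376.88,177.63,-225.54,5.35
18,2,5,27,5,435.49,177.63,-297.52,5.35
19,2,5,28,5,508.50,177.63,-386.21,5.35
20,2,5,29,5,601.93,177.63,-497.64,5.35
21,2,5,30,5,725.76,177.63,-641.77,5.35
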