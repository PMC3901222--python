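instance,actual_tbsa,pred_2var,pred_3var,pred_4var,pred_5var
1,0,0.132,0.324,1.35,1.271
2,0,-0.281,-0.373,-0.423,-0.320
3,0,3.003,0.109,0.05,-0.195
4,0,-0.614,0.415,-0.632,-0.520
5,0,0.309,-0.713,-0.011,-0.013
6,0,-0.416,-0.213,-0.451,-0.635
7,0,-0.281,0.079,-0.301,-0.229
8,20,19.048,19.876,20.654,20.528
9,20,19.048,20.171,18.383,18.014
10,20,19.048,19.585,19.72,19.590
11,20,19.048,19.585,19.72,19.590
12,20,25.415,19.686,19.993,19.715
13,20,19.048,19.510,18.22,17.947
14,20,20.255,20.757,20.651,17.947
15,40,40.709,39.911,39.795,39.246
16,40,40.957,40.268,40.919,40.870
17,40,40.709,40.091,40.045,39.633
18,40,41.238,39.938,39.866,39.709
19,40,41.221,38.822,39.612,39.620
20,40,39.865,39.757,38.984,38.333
21,40,36.667,39.739,39.708,39.546
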