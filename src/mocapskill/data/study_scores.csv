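participant,cycle,baba,dvss,mc
1,1,26,80,39.3
1,2,35,91,85.7
2,1,18,57,33.0
2,2,36,82,89.9
3,1,19,64,69.8
3,2,23,73,39.3
4,1,15,62,28.9
4,2,32,87,60.0
5,1,20,64,45.2
5,2,28,84,56.8
6,1,11,1,16.4
6,2,18,55,20.3
7,1,20,56,58.8
7,2,24,89,77.7
8,1,13,61,35.3
8,2,25,80,52.6
9,1,17,80,55.6
9,2,25,89,64.7
10,1,22,67,57.5
10,2,29,71,79.6
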