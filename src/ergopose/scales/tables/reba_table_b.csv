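upper_arm,lower_arm,wrist,score
1,1,1,1
1,1,2,2
1,1,3,2
2,1,1,1
2,1,2,2
2,1,3,3
3,1,1,3
3,1,2,4
3,1,3,5
4,1,1,4
4,1,2,5
4,1,3,5
5,1,1,6
5,1,2,7
5,1,3,8
6,1,1,7
6,1,2,8
6,1,3,8
1,2,1,1
1,2,2,2
1,2,3,3
2,2,1,2
2,2,2,3
2,2,3,4
3,2,1,4
3,2,2,5
3,2,3,5
4,2,1,5
4,2,2,6
4,2,3,7
5,2,1,8
5,2,2,8
5,2,3,9
6,2,1,8
6,2,2,9
6,2,3,9
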