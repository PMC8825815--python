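trunk,neck,legs,score
1,1,1,1
1,1,2,2
1,1,3,3
1,1,4,4
2,1,1,2
2,1,2,3
2,1,3,4
2,1,4,5
3,1,1,2
3,1,2,4
3,1,3,5
3,1,4,6
4,1,1,3
4,1,2,5
4,1,3,6
4,1,4,7
5,1,1,4
5,1,2,6
5,1,3,7
5,1,4,8
1,2,1,1
1,2,2,2
1,2,3,3
1,2,4,4
2,2,1,3
2,2,2,4
2,2,3,5
2,2,4,6
3,2,1,4
3,2,2,5
3,2,3,6
3,2,4,7
4,2,1,5
4,2,2,6
4,2,3,7
4,2,4,8
5,2,1,6
5,2,2,7
5,2,3,8
5,2,4,9
1,3,1,3
1,3,2,3
1,3,3,5
1,3,4,6
2,3,1,4
2,3,2,5
2,3,3,6
2,3,4,7
3,3,1,5
3,3,2,6
3,3,3,7
3,3,4,8
4,3,1,6
4,3,2,7
4,3,3,8
4,3,4,9
5,3,1,7
5,3,2,8
5,3,3,9
5,3,4,9
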