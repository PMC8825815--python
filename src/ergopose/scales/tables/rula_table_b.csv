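neck,trunk,legs,score
1,1,1,1
1,1,2,3
1,2,1,2
1,2,2,3
1,3,1,3
1,3,2,4
1,4,1,5
1,4,2,5
1,5,1,6
1,5,2,6
1,6,1,7
1,6,2,7
2,1,1,2
2,1,2,3
2,2,1,2
2,2,2,3
2,3,1,4
2,3,2,5
2,4,1,5
2,4,2,5
2,5,1,6
2,5,2,7
2,6,1,7
2,6,2,7
3,1,1,3
3,1,2,3
3,2,1,3
3,2,2,4
3,3,1,4
3,3,2,5
3,4,1,5
3,4,2,6
3,5,1,6
3,5,2,7
3,6,1,7
3,6,2,7
4,1,1,5
4,1,2,5
4,2,1,5
4,2,2,6
4,3,1,6
4,3,2,7
4,4,1,7
4,4,2,7
4,5,1,7
4,5,2,7
4,6,1,8
4,6,2,8
5,1,1,7
5,1,2,7
5,2,1,7
5,2,2,7
5,3,1,7
5,3,2,8
5,4,1,8
5,4,2,8
5,5,1,8
5,5,2,8
5,6,1,8
5,6,2,8
6,1,1,8
6,1,2,8
6,2,1,8
6,2,2,8
6,3,1,8
6,3,2,8
6,4,1,8
6,4,2,9
6,5,1,9
6,5,2,9
6,6,1,9
6,6,2,9
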