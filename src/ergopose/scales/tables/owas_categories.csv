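back,arms,legs,load,category
1,1,1,1,1
1,1,1,2,1
1,1,1,3,1
1,1,2,1,1
1,1,2,2,1
1,1,2,3,1
1,1,3,1,1
1,1,3,2,1
1,1,3,3,1
1,1,4,1,2
1,1,4,2,2
1,1,4,3,2
1,1,5,1,2
1,1,5,2,2
1,1,5,3,2
1,1,6,1,1
1,1,6,2,1
1,1,6,3,1
1,1,7,1,1
1,1,7,2,1
1,1,7,3,1
1,2,1,1,1
1,2,1,2,1
1,2,1,3,1
1,2,2,1,1
1,2,2,2,1
1,2,2,3,1
1,2,3,1,1
1,2,3,2,1
1,2,3,3,1
1,2,4,1,2
1,2,4,2,2
1,2,4,3,2
1,2,5,1,2
1,2,5,2,2
1,2,5,3,2
1,2,6,1,1
1,2,6,2,1
1,2,6,3,1
1,2,7,1,1
1,2,7,2,1
1,2,7,3,1
1,3,1,1,1
1,3,1,2,1
1,3,1,3,1
1,3,2,1,1
1,3,2,2,1
1,3,2,3,1
1,3,3,1,1
1,3,3,2,1
1,3,3,3,2
1,3,4,1,2
1,3,4,2,2
1,3,4,3,3
1,3,5,1,2
1,3,5,2,2
1,3,5,3,2
1,3,6,1,1
1,3,6,2,1
1,3,6,3,1
1,3,7,1,1
1,3,7,2,1
1,3,7,3,2
2,1,1,1,2
2,1,1,2,2
2,1,1,3,3
2,1,2,1,2
2,1,2,2,2
2,1,2,3,3
2,1,3,1,2
2,1,3,2,2
2,1,3,3,3
2,1,4,1,3
2,1,4,2,3
2,1,4,3,3
2,1,5,1,3
2,1,5,2,3
2,1,5,3,3
2,1,6,1,2
2,1,6,2,2
2,1,6,3,2
2,1,7,1,2
2,1,7,2,3
2,1,7,3,3
2,2,1,1,2
2,2,1,2,2
2,2,1,3,3
2,2,2,1,2
2,2,2,2,2
2,2,2,3,3
2,2,3,1,2
2,2,3,2,3
2,2,3,3,3
2,2,4,1,3
2,2,4,2,4
2,2,4,3,4
2,2,5,1,3
2,2,5,2,4
2,2,5,3,4
2,2,6,1,3
2,2,6,2,3
2,2,6,3,4
2,2,7,1,2
2,2,7,2,3
2,2,7,3,4
2,3,1,1,3
2,3,1,2,3
2,3,1,3,4
2,3,2,1,2
2,3,2,2,2
2,3,2,3,3
2,3,3,1,3
2,3,3,2,3
2,3,3,3,3
2,3,4,1,3
2,3,4,2,4
2,3,4,3,4
2,3,5,1,4
2,3,5,2,4
2,3,5,3,4
2,3,6,1,4
2,3,6,2,4
2,3,6,3,4
2,3,7,1,2
2,3,7,2,3
2,3,7,3,4
3,1,1,1,1
3,1,1,2,1
3,1,1,3,1
3,1,2,1,1
3,1,2,2,1
3,1,2,3,1
3,1,3,1,1
3,1,3,2,1
3,1,3,3,2
3,1,4,1,3
3,1,4,2,3
3,1,4,3,3
3,1,5,1,4
3,1,5,2,4
3,1,5,3,4
3,1,6,1,1
3,1,6,2,1
3,1,6,3,1
3,1,7,1,1
3,1,7,2,1
3,1,7,3,1
3,2,1,1,2
3,2,1,2,2
3,2,1,3,3
3,2,2,1,1
3,2,2,2,1
3,2,2,3,1
3,2,3,1,1
3,2,3,2,1
3,2,3,3,2
3,2,4,1,4
3,2,4,2,4
3,2,4,3,4
3,2,5,1,4
3,2,5,2,4
3,2,5,3,4
3,2,6,1,3
3,2,6,2,3
3,2,6,3,3
3,2,7,1,1
3,2,7,2,1
3,2,7,3,1
3,3,1,1,2
3,3,1,2,2
3,3,1,3,3
3,3,2,1,1
3,3,2,2,1
3,3,2,3,1
3,3,3,1,2
3,3,3,2,3
3,3,3,3,3
3,3,4,1,4
3,3,4,2,4
3,3,4,3,4
3,3,5,1,4
3,3,5,2,4
3,3,5,3,4
3,3,6,1,4
3,3,6,2,4
3,3,6,3,4
3,3,7,1,1
3,3,7,2,1
3,3,7,3,1
4,1,1,1,2
4,1,1,2,3
4,1,1,3,3
4,1,2,1,2
4,1,2,2,2
4,1,2,3,3
4,1,3,1,2
4,1,3,2,2
4,1,3,3,3
4,1,4,1,4
4,1,4,2,4
4,1,4,3,4
4,1,5,1,4
4,1,5,2,4
4,1,5,3,4
4,1,6,1,4
4,1,6,2,4
4,1,6,3,4
4,1,7,1,2
4,1,7,2,3
4,1,7,3,4
4,2,1,1,3
4,2,1,2,3
4,2,1,3,4
4,2,2,1,2
4,2,2,2,3
4,2,2,3,4
4,2,3,1,3
4,2,3,2,3
4,2,3,3,4
4,2,4,1,4
4,2,4,2,4
4,2,4,3,4
4,2,5,1,4
4,2,5,2,4
4,2,5,3,4
4,2,6,1,4
4,2,6,2,4
4,2,6,3,4
4,2,7,1,2
4,2,7,2,3
4,2,7,3,4
4,3,1,1,4
4,3,1,2,4
4,3,1,3,4
4,3,2,1,2
4,3,2,2,3
4,3,2,3,4
4,3,3,1,3
4,3,3,2,3
4,3,3,3,4
4,3,4,1,4
4,3,4,2,4
4,3,4,3,4
4,3,5,1,4
4,3,5,2,4
4,3,5,3,4
4,3,6,1,4
4,3,6,2,4
4,3,6,3,4
4,3,7,1,2
4,3,7,2,3
4,3,7,3,4
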