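rank,S1,S2,S3,S4,S5,S6,S7,S8,S9
1,3,4.1,7.3,3.5,2.2,5,2.4,2.6,2.3
2,4,6.3,9.2,4.9,3.8,6.3,3.3,2.8,2.9
3,4.4,7,10.5,5.4,4.2,6.5,3.5,3,3.2
4,5.1,7.9,11.3,6.2,5,8.3,4.2,3.8,4
5,5.7,9.3,12.5,7,5.4,8.6,4.3,4,4.4
6,6.8,10,15.3,8.2,6,9.5,5.4,4.4,5
7,7.8,11.7,17,9.9,6.9,11.5,6.4,5.3,5.8
8,8.8,13.7,17.4,10.6,7,13.2,7.4,5.7,6
9,10.2,15.8,21,12.2,8.6,15.3,8.1,6,7.4
10,12,17.8,23.3,13.3,9.2,17.7,9.6,7.2,8.8
11,12.9,21.7,29.2,16,10.8,20.6,11.1,8.2,9.4
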