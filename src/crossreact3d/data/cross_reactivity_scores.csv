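molecule_id,score
10,15
22,56
23,3
25,39
29,13
30,16
37,6
56,11
58,3
60,9
71,15
72,12
100,-17
101,-17
102,-17
103,-17
104,-17
105,-17
106,-17
107,-17
108,-17
109,-17
110,-17
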