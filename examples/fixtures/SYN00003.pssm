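
Last position-specific scoring matrix computed
    A C D E F G H I K L M N P Q R S T V W Y  A C D E F G H I K L M N P Q R S T V W Y
1 P 1.0 1.0 1.0 -1.0 -0.0 0.0 2.0 1.0 -0.0 0.0 0.0 -0.0 1.0 1.0 2.0 2.0 0.0 -1.0 -1.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
2 M 1.0 2.0 0.0 0.0 -0.0 1.0 -2.0 -2.0 -2.0 -0.0 -0.0 1.0 0.0 1.0 -0.0 -0.0 -1.0 0.0 -0.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
3 N -1.0 -1.0 -1.0 1.0 0.0 1.0 -1.0 -1.0 1.0 -1.0 -1.0 1.0 1.0 1.0 0.0 -1.0 0.0 1.0 -0.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
4 G 1.0 2.0 -2.0 0.0 -2.0 0.0 -0.0 2.0 1.0 -1.0 2.0 -2.0 1.0 2.0 0.0 1.0 1.0 -0.0 0.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
5 I 1.0 -1.0 1.0 -0.0 -0.0 -0.0 -1.0 1.0 -0.0 -1.0 -0.0 -0.0 0.0 0.0 -0.0 0.0 2.0 -0.0 -3.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
6 W -1.0 1.0 1.0 -0.0 0.0 -0.0 -1.0 0.0 0.0 -1.0 0.0 1.0 -2.0 0.0 1.0 1.0 -1.0 -0.0 0.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
7 A 2.0 0.0 1.0 -0.0 -0.0 1.0 2.0 2.0 -1.0 -1.0 2.0 -2.0 -0.0 -1.0 1.0 0.0 1.0 0.0 -0.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
8 D -1.0 -1.0 -0.0 -0.0 -1.0 0.0 2.0 -0.0 1.0 -0.0 1.0 -1.0 1.0 0.0 0.0 -1.0 -0.0 1.0 -2.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
9 G 0.0 2.0 1.0 1.0 -0.0 0.0 -1.0 -0.0 0.0 -1.0 1.0 0.0 -0.0 -1.0 1.0 1.0 -0.0 -1.0 1.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
10 Q 1.0 0.0 1.0 -0.0 2.0 1.0 -1.0 -0.0 2.0 0.0 -1.0 0.0 1.0 0.0 -0.0 -2.0 2.0 -1.0 1.0 -2.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
11 C -1.0 -1.0 1.0 -1.0 1.0 2.0 0.0 -1.0 -0.0 -1.0 1.0 1.0 0.0 -1.0 -2.0 -0.0 -0.0 -1.0 -1.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
12 K 1.0 -2.0 -0.0 1.0 -2.0 -0.0 0.0 0.0 2.0 -0.0 -1.0 -0.0 0.0 -1.0 -2.0 -1.0 -0.0 2.0 -1.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
13 S -1.0 1.0 0.0 1.0 0.0 -1.0 0.0 -1.0 0.0 1.0 3.0 -1.0 1.0 1.0 -1.0 0.0 1.0 -1.0 0.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
14 D 0.0 -1.0 0.0 0.0 -1.0 -1.0 -0.0 -1.0 0.0 -1.0 1.0 0.0 -1.0 1.0 -1.0 -0.0 1.0 -1.0 2.0 -2.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
15 K -3.0 0.0 -1.0 0.0 -1.0 -0.0 0.0 0.0 -0.0 -0.0 -0.0 -1.0 1.0 -1.0 0.0 0.0 -2.0 0.0 1.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
16 L 1.0 -0.0 0.0 1.0 -0.0 1.0 -2.0 0.0 -2.0 -0.0 -1.0 0.0 -0.0 2.0 -0.0 -1.0 -2.0 -0.0 -0.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
17 Q 1.0 1.0 -1.0 -1.0 -0.0 -1.0 0.0 -0.0 1.0 -1.0 -2.0 1.0 3.0 1.0 -2.0 -1.0 2.0 -0.0 -0.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
18 F 1.0 0.0 -1.0 -1.0 -0.0 -0.0 1.0 -1.0 -0.0 2.0 2.0 2.0 0.0 1.0 -1.0 -1.0 -1.0 0.0 1.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
19 T -0.0 -0.0 1.0 -1.0 0.0 1.0 1.0 0.0 1.0 0.0 -0.0 -2.0 -2.0 0.0 -0.0 2.0 0.0 2.0 -1.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
20 V 1.0 1.0 -1.0 -1.0 -1.0 2.0 1.0 1.0 -1.0 2.0 1.0 -1.0 -1.0 -0.0 1.0 -0.0 1.0 -1.0 1.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
21 G 1.0 -1.0 1.0 -1.0 1.0 -1.0 -0.0 1.0 -1.0 -2.0 -1.0 -0.0 -0.0 0.0 -0.0 0.0 -1.0 -0.0 0.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
22 N -1.0 -0.0 2.0 2.0 -2.0 -0.0 -0.0 -0.0 -0.0 -1.0 -0.0 -1.0 -2.0 -1.0 -0.0 1.0 2.0 -1.0 1.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
23 V -0.0 1.0 -0.0 -1.0 -1.0 -1.0 -1.0 0.0 0.0 -1.0 -2.0 1.0 -0.0 -0.0 -0.0 -0.0 -1.0 1.0 1.0 0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
24 L -3.0 0.0 0.0 1.0 0.0 1.0 -0.0 -2.0 2.0 2.0 1.0 -2.0 1.0 -0.0 -1.0 1.0 3.0 0.0 -0.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
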