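
Last position-specific scoring matrix computed
    A C D E F G H I K L M N P Q R S T V W Y  A C D E F G H I K L M N P Q R S T V W Y
1 W 3.0 1.0 -0.0 -0.0 4.0 -2.0 1.0 -1.0 1.0 0.0 5.0 -1.0 -0.0 0.0 -2.0 1.0 5.0 5.0 4.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
2 C 6.0 1.0 0.0 0.0 5.0 -1.0 1.0 -2.0 -0.0 0.0 6.0 2.0 1.0 -0.0 1.0 -1.0 6.0 5.0 4.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
3 T 3.0 -0.0 2.0 -1.0 4.0 0.0 0.0 0.0 -0.0 -1.0 3.0 -1.0 0.0 1.0 -1.0 -1.0 3.0 3.0 2.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
4 Y 0.0 -1.0 0.0 -0.0 -0.0 0.0 1.0 2.0 2.0 -0.0 -0.0 0.0 0.0 -1.0 -1.0 1.0 2.0 -0.0 -1.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
5 D -5.0 -0.0 0.0 -0.0 -2.0 0.0 0.0 -0.0 1.0 -1.0 -4.0 -1.0 1.0 1.0 -1.0 2.0 -4.0 -5.0 -4.0 0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
6 R -5.0 2.0 1.0 2.0 -4.0 -2.0 -0.0 -3.0 -1.0 1.0 -6.0 -1.0 0.0 1.0 -0.0 -0.0 -4.0 -5.0 -5.0 0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
7 L -3.0 0.0 2.0 -0.0 -4.0 1.0 -1.0 2.0 -0.0 0.0 -3.0 1.0 1.0 -0.0 -0.0 0.0 -3.0 -4.0 -3.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
8 N 0.0 2.0 0.0 -0.0 0.0 -1.0 -1.0 0.0 -1.0 -0.0 -0.0 0.0 0.0 0.0 -2.0 -0.0 -1.0 -0.0 1.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
9 Y 4.0 1.0 -1.0 0.0 4.0 -1.0 0.0 -0.0 1.0 1.0 3.0 1.0 -0.0 2.0 -0.0 0.0 4.0 3.0 2.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
10 I 6.0 -0.0 -0.0 2.0 5.0 1.0 1.0 -1.0 0.0 0.0 5.0 -1.0 0.0 -2.0 -1.0 -1.0 5.0 6.0 7.0 2.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
11 G 4.0 0.0 -2.0 1.0 6.0 0.0 0.0 1.0 1.0 0.0 3.0 0.0 -1.0 -2.0 1.0 -0.0 4.0 5.0 5.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
12 F 0.0 -1.0 -0.0 1.0 0.0 -3.0 -2.0 -1.0 1.0 0.0 0.0 -1.0 0.0 -2.0 0.0 1.0 -1.0 1.0 -1.0 0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
13 E -4.0 0.0 2.0 1.0 -4.0 -3.0 1.0 1.0 0.0 -1.0 -2.0 -2.0 -1.0 -1.0 0.0 -0.0 -1.0 -4.0 -4.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
14 Y -6.0 -1.0 1.0 -0.0 -4.0 0.0 0.0 0.0 -0.0 0.0 -5.0 -2.0 0.0 -0.0 -1.0 1.0 -5.0 -7.0 -5.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
15 F -5.0 0.0 -1.0 1.0 -4.0 1.0 0.0 0.0 -1.0 1.0 -3.0 -0.0 1.0 -1.0 -1.0 -0.0 -3.0 -3.0 -3.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
16 F -1.0 1.0 0.0 1.0 0.0 0.0 2.0 1.0 1.0 -0.0 0.0 -2.0 -1.0 1.0 -2.0 0.0 0.0 0.0 -2.0 -2.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
17 M 5.0 0.0 0.0 2.0 4.0 -2.0 -0.0 1.0 -0.0 -0.0 3.0 1.0 1.0 -2.0 2.0 -1.0 6.0 2.0 5.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
18 V 5.0 1.0 -1.0 0.0 5.0 1.0 1.0 2.0 0.0 0.0 4.0 -1.0 -1.0 -0.0 0.0 0.0 6.0 4.0 7.0 0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
19 T 5.0 0.0 -1.0 -0.0 0.0 0.0 -0.0 1.0 -2.0 -0.0 3.0 -1.0 -1.0 -1.0 1.0 1.0 2.0 3.0 4.0 0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
20 C -2.0 -1.0 -1.0 1.0 3.0 -0.0 -2.0 1.0 2.0 1.0 0.0 1.0 0.0 1.0 1.0 -1.0 -1.0 -0.0 -0.0 0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
21 D -2.0 -1.0 1.0 -0.0 -6.0 -0.0 -0.0 1.0 1.0 -0.0 -4.0 1.0 -1.0 -1.0 -1.0 -1.0 -4.0 -4.0 -4.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
22 T -4.0 1.0 -0.0 -1.0 -5.0 -0.0 1.0 -0.0 -1.0 -1.0 -3.0 -1.0 -1.0 -0.0 2.0 0.0 -5.0 -7.0 -6.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
23 R -4.0 0.0 -1.0 1.0 -2.0 -2.0 0.0 -0.0 1.0 0.0 -3.0 -0.0 0.0 2.0 2.0 -2.0 -3.0 -3.0 -5.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
24 V 0.0 1.0 1.0 -0.0 -1.0 -2.0 2.0 -1.0 -1.0 0.0 -0.0 -0.0 1.0 -0.0 -1.0 -0.0 0.0 -1.0 -1.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
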