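
Last position-specific scoring matrix computed
    A C D E F G H I K L M N P Q R S T V W Y  A C D E F G H I K L M N P Q R S T V W Y
1 F 3.0 -2.0 0.0 1.0 5.0 2.0 1.0 -0.0 1.0 -1.0 4.0 -0.0 -2.0 -0.0 0.0 -1.0 4.0 5.0 2.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
2 Y 6.0 -1.0 -0.0 -1.0 4.0 -0.0 1.0 -1.0 -2.0 -3.0 4.0 -1.0 0.0 0.0 -2.0 0.0 5.0 5.0 4.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
3 N 4.0 0.0 1.0 0.0 4.0 1.0 -0.0 -1.0 2.0 1.0 2.0 -1.0 -1.0 -2.0 0.0 2.0 4.0 5.0 3.0 0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
4 Q -1.0 0.0 1.0 1.0 1.0 -0.0 1.0 1.0 1.0 -1.0 0.0 0.0 -1.0 -1.0 -1.0 1.0 0.0 2.0 -2.0 0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
5 C -2.0 2.0 -1.0 2.0 -2.0 1.0 0.0 1.0 1.0 -1.0 -6.0 1.0 1.0 1.0 -0.0 -0.0 -5.0 -2.0 -4.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
6 R -5.0 -2.0 1.0 1.0 -3.0 -0.0 -0.0 0.0 -1.0 -1.0 -4.0 -0.0 -1.0 0.0 -0.0 2.0 -5.0 -3.0 -4.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
7 R -3.0 -0.0 0.0 -1.0 -3.0 1.0 -2.0 -1.0 -1.0 1.0 -3.0 -0.0 2.0 -0.0 1.0 1.0 -4.0 -2.0 -4.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
8 A 0.0 1.0 1.0 -1.0 -1.0 1.0 -2.0 0.0 1.0 -2.0 -1.0 -0.0 -0.0 -0.0 0.0 1.0 -2.0 1.0 -0.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
9 A 5.0 -1.0 -1.0 -2.0 5.0 -2.0 -1.0 -2.0 -0.0 -2.0 5.0 -1.0 -1.0 0.0 -1.0 -0.0 4.0 3.0 3.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
10 M 5.0 3.0 -2.0 1.0 5.0 -1.0 1.0 1.0 -1.0 -0.0 4.0 0.0 0.0 -0.0 0.0 1.0 6.0 4.0 5.0 2.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
11 A 3.0 1.0 -1.0 1.0 3.0 0.0 -0.0 1.0 -0.0 -0.0 4.0 -1.0 -2.0 -1.0 -1.0 2.0 6.0 2.0 4.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
12 I 0.0 -1.0 0.0 -1.0 -1.0 -1.0 -2.0 1.0 -1.0 1.0 1.0 1.0 -0.0 1.0 1.0 -0.0 0.0 1.0 0.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
13 Y -2.0 1.0 -1.0 0.0 -3.0 1.0 -1.0 1.0 1.0 -0.0 -4.0 -1.0 1.0 -1.0 -0.0 2.0 -3.0 -3.0 -3.0 -0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
14 W -6.0 1.0 -1.0 2.0 -7.0 -0.0 0.0 -1.0 0.0 1.0 -4.0 0.0 0.0 0.0 0.0 -1.0 -5.0 -4.0 -5.0 0.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
15 I -4.0 1.0 0.0 0.0 -4.0 -2.0 -1.0 -0.0 -1.0 1.0 -4.0 -2.0 1.0 -0.0 0.0 -2.0 -4.0 -4.0 -3.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
16 Y -1.0 -0.0 2.0 -0.0 1.0 -2.0 -0.0 1.0 1.0 2.0 -0.0 0.0 -2.0 -1.0 1.0 -1.0 1.0 -0.0 1.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
17 N 2.0 1.0 1.0 0.0 4.0 1.0 1.0 -0.0 -1.0 0.0 4.0 -1.0 -2.0 0.0 1.0 0.0 3.0 4.0 4.0 -1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
18 M 5.0 1.0 0.0 -0.0 6.0 1.0 -1.0 1.0 1.0 0.0 5.0 0.0 -1.0 1.0 0.0 1.0 4.0 4.0 4.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
19 L 4.0 -1.0 -1.0 3.0 4.0 -1.0 -0.0 1.0 -0.0 -1.0 3.0 2.0 1.0 1.0 -1.0 -1.0 3.0 3.0 4.0 1.0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0
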