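res	class	eps_i
A	H	0.400000
C	H	0.555556
D	E	-0.777778
E	E	-0.777778
F	H	0.622222
G	P	-0.088889
H	E	-0.711111
I	H	1.000000
K	E	-0.866667
L	H	0.844444
M	H	0.422222
N	P	-0.777778
P	P	-0.355556
Q	P	-0.777778
R	E	-1.000000
S	P	-0.177778
T	P	-0.155556
V	H	0.933333
W	P	-0.200000
Y	P	-0.288889
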