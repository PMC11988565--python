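# Residue retention coefficients for RP-HPLC at pH 2
# Guo, Mant, Parker & Hodges (1986), J. Chromatogr. 359, 499-518.
# Arbitrary retention units; leucine > isoleucine, the ordering that makes
# I/L sequence isoforms chromatographically separable.
W	8.8
F	8.1
L	8.1
I	7.4
M	5.5
V	5.0
Y	4.5
C	2.6
A	2.0
P	2.0
E	1.1
T	0.6
D	0.2
Q	0.0
S	-0.2
G	-0.2
R	-0.6
N	-0.6
H	-2.1
K	-2.1
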