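# Unfolded-state cis fractions of Xaa-Pro imide bonds, per preceding
# residue Xaa, from model-compound peptide studies (values span roughly
# 6-38%: aromatic Xaa favour cis strongly, beta-branched Xaa weakly).
# Used to build the unfolded-state isomer equilibrium constant K:
#   native-trans proline: K = f_cis / (1 - f_cis)
#   native-cis  proline: K = (1 - f_cis) / f_cis
# The table is a default; a user-supplied table (same format) can replace
# it when protein-derived K values are available.
# xaa	f_cis
A	0.11
R	0.11
N	0.12
D	0.12
C	0.10
Q	0.11
E	0.11
G	0.14
H	0.13
I	0.08
L	0.10
K	0.11
M	0.11
F	0.21
P	0.12
S	0.13
T	0.10
W	0.38
Y	0.25
V	0.08
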