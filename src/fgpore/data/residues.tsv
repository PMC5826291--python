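# one-bead-per-amino-acid bead parameters
# lambda: Fauchere-Pliska octanol partition energies, min-max normalized to [0,1]
code	mass_da	charge_e	lambda	diameter_nm
A	71.0788	0	0.4049	0.6
C	103.1388	0	0.7822	0.6
D	115.0886	-1	0.0736	0.6
E	129.1155	-1	0.1135	0.6
F	147.1766	0	0.8589	0.6
G	57.0519	0	0.3098	0.6
H	137.1411	0	0.3497	0.6
I	113.1594	0	0.8620	0.6
K	128.1741	1	0.0061	0.6
L	113.1594	0	0.8313	0.6
M	131.1926	0	0.6871	0.6
N	114.1038	0	0.1258	0.6
P	97.1167	0	0.5307	0.6
Q	128.1307	0	0.2423	0.6
R	156.1875	1	0.0000	0.6
S	87.0782	0	0.2975	0.6
T	101.1051	0	0.3896	0.6
V	99.1326	0	0.6840	0.6
W	186.2132	0	1.0000	0.6
Y	163.1760	0	0.6043	0.6
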