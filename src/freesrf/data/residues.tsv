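# Per-residue (in-chain, water-condensed) polarizability contributions and masses.
# alpha_A3: static electronic polarizability of the residue, Angstrom^3, obtained by
#   atom-count additivity over the residue elemental formula using the atomic values in
#   atoms.tsv (classic sodium-D atomic refraction increments converted via
#   alpha = 3R/(4*pi*N_A)).  Frozen here so the table is an independent, versioned input.
# mass_gmol: monoisotopic-free average residue mass (free amino acid minus one water).
# code	alpha_A3	mass_gmol	source
A	6.628	71.079	atom-additive over C3H5NO
R	15.320	156.189	atom-additive over C6H12N4O
N	9.594	114.104	atom-additive over C4H6N2O2
D	8.887	115.088	atom-additive over C4H5NO3
C	9.678	103.139	atom-additive over C3H5NOS
Q	11.425	128.131	atom-additive over C5H8N2O2
E	10.718	129.115	atom-additive over C5H7NO3
G	4.797	57.052	atom-additive over C2H3NO
H	12.219	137.142	atom-additive over C6H7N3O
I	12.121	113.160	atom-additive over C6H11NO
L	12.121	113.160	atom-additive over C6H11NO
K	13.478	128.175	atom-additive over C6H12N2O
M	13.340	131.193	atom-additive over C5H9NOS
F	14.126	147.177	atom-additive over C9H9NO
P	9.418	97.117	atom-additive over C5H7NO
S	7.278	87.078	atom-additive over C3H5NO2
T	9.109	101.105	atom-additive over C4H7NO2
W	17.401	186.214	atom-additive over C11H10N2O
Y	14.776	163.176	atom-additive over C9H9NO2
V	10.290	99.133	atom-additive over C5H9NO
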