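# Atomic polarizability contributions for the additive small-molecule model, plus
# monatomic-ion entries usable as ligands.
# alpha_A3: neutral atoms — converted from classic sodium-D atomic refraction
#   increments (Eisenlohr/Vogel), alpha = 3R/(4*pi*N_A); this convention reproduces
#   the 1.5 A^3 solvation-shell water benchmark (H2O -> 1.52 A^3).
#   Ions — Pauling free-ion polarizabilities.
# radius_A: ionic radius (Shannon, 6-coordinate) for monatomic ions; '-' for neutral
#   atoms (their geometry comes from molar mass, not this table).
# symbol	alpha_A3	mass_gmol	radius_A	source
H	0.436	1.008	-	atomic refraction R=1.100 cm3/mol
C	0.959	12.011	-	atomic refraction R=2.418 cm3/mol
N	0.921	14.007	-	atomic refraction R=2.322 cm3/mol
O	0.650	15.999	-	atomic refraction R=1.64 cm3/mol
S	3.050	32.06	-	atomic refraction R=7.69 cm3/mol
P	1.743	30.974	-	atomic refraction R=4.40 cm3/mol
Ca2+	0.470	40.078	1.00	Pauling ion polarizability; Shannon radius
Mg2+	0.094	24.305	0.72	Pauling ion polarizability; Shannon radius
Zn2+	0.290	65.38	0.74	Pauling ion polarizability; Shannon radius
Na+	0.180	22.990	1.02	Pauling ion polarizability; Shannon radius
K+	0.840	39.098	1.38	Pauling ion polarizability; Shannon radius
Cl-	3.660	35.45	1.81	Pauling ion polarizability; Shannon radius
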