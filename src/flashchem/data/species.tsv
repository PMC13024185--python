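# Species table for the aerated cellular-water radiolysis scheme (25 C).
# Columns: name, D (nm^2/ns == 1e-9 m^2/s), charge (units of e), notes
# Diffusion coefficients are standard 25 C water-radiolysis values
# (Elliot/Buxton compilations); bulky solutes (RH, GSH, AH-, TOH) appear here
# for referential completeness but are treated as continuum scavengers, never
# as diffusing particles.
name	D	charge	notes
e-aq	4.9	-1	hydrated electron
H	7.0	0	hydrogen atom
H2	4.8	0	molecular hydrogen
OH	2.2	0	hydroxyl radical
H2O2	2.3	0	hydrogen peroxide
H+	9.5	1	hydronium ion (H3O+)
OH-	5.3	-1	hydroxide ion
O2	2.4	0	dissolved molecular oxygen (continuum solute)
O2-	1.75	-1	superoxide radical anion
HO2	2.0	0	hydroperoxyl radical
HO2-	1.4	-1	hydroperoxide anion
RH	0.05	0	generic oxidizable biomolecule pool (continuum, 1 M)
R	0.1	0	carbon-centred bio-radical (macromolecule-bound, quasi-immobile)
ROO	0.1	0	organic peroxyl radical
ROOH	0.1	0	organic hydroperoxide
RR	0.05	0	R-R recombination dimer (closed shell)
RNO	0.1	0	nitroso adduct of R
GSH	0.3	0	glutathione (continuum, 6.5 mM)
GS	0.5	0	glutathiyl radical
GSSG-	0.4	-1	glutathione disulfide radical anion
GSSG	0.4	0	glutathione disulfide (closed shell)
AH-	0.5	-1	ascorbate monoanion (continuum, 1 mM)
A-	0.5	-1	ascorbyl radical anion (terminal on these time scales)
NO	2.0	0	nitric oxide (continuum, 1 uM, depletable)
ONOO-	1.0	-1	peroxynitrite
TOH	0.05	0	alpha-tocopherol (continuum, 0.2 mM)
TO	0.05	0	tocopheroxyl radical
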