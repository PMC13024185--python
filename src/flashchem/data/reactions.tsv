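# Reaction scheme: pure-water radiolysis core (25 C) + cellular extension.
# Columns: id, reactant1, reactant2 (blank for first-order), products
# (semicolon-separated; blank if all products are water/implicit), k, units,
# class, radius_nm (physical encounter radius, used for the
# partially-diffusion-controlled Collins-Kimball split; blank = derived),
# source.
# Rate-constant convention for identical reactants: k is the event rate
# constant (d[A]/dt = -2 k [A]^2).
# Classes: fully-diffusion-controlled | partially-diffusion-controlled |
#          background-scavenging | first-order
# Sources: "elliot/buxton" = standard 25 C compilations of water radiolysis
# rate constants; "printed" = the four cellular reactions with printed rate
# constants (R1-R4); "literature" = standard antioxidant/bio-radical pulse
# radiolysis values; "model" = package default documented in docs/methods.md.
id	reactant1	reactant2	products	k	units	class	radius_nm	source
W01	e-aq	e-aq	H2;OH-;OH-	5.5e9	M-1s-1	fully-diffusion-controlled		elliot/buxton
W02	e-aq	OH	OH-	3.0e10	M-1s-1	fully-diffusion-controlled		elliot/buxton
W03	e-aq	H	H2;OH-	2.5e10	M-1s-1	fully-diffusion-controlled		elliot/buxton
W04	e-aq	H+	H	2.3e10	M-1s-1	partially-diffusion-controlled	0.30	elliot/buxton
W05	e-aq	H2O2	OH;OH-	1.1e10	M-1s-1	fully-diffusion-controlled		elliot/buxton
W06	e-aq	O2	O2-	1.9e10	M-1s-1	background-scavenging		elliot/buxton
W07	OH	OH	H2O2	5.5e9	M-1s-1	fully-diffusion-controlled		elliot/buxton
W08	OH	H		7.0e9	M-1s-1	fully-diffusion-controlled		elliot/buxton
W09	OH	H2	H	4.2e7	M-1s-1	partially-diffusion-controlled	0.40	elliot/buxton
W10	OH	H2O2	HO2	2.7e7	M-1s-1	partially-diffusion-controlled	0.40	elliot/buxton
W11	H	H	H2	7.8e9	M-1s-1	fully-diffusion-controlled		elliot/buxton
W12	H	H2O2	OH	9.0e7	M-1s-1	partially-diffusion-controlled	0.40	elliot/buxton
W13	H	O2	HO2	2.1e10	M-1s-1	background-scavenging		elliot/buxton
W14	H+	OH-		1.1e11	M-1s-1	fully-diffusion-controlled		elliot/buxton
W15	OH	O2-	O2;OH-	8.0e9	M-1s-1	fully-diffusion-controlled		elliot/buxton
W16	OH	HO2	O2	6.0e9	M-1s-1	fully-diffusion-controlled		elliot/buxton
W17	e-aq	O2-	HO2-;OH-	1.3e10	M-1s-1	fully-diffusion-controlled		elliot/buxton
W18	e-aq	HO2	HO2-	2.0e10	M-1s-1	fully-diffusion-controlled		elliot/buxton
W19	H	O2-	HO2-	2.0e10	M-1s-1	fully-diffusion-controlled		elliot/buxton
W20	HO2		O2-;H+	8.0e5	s-1	first-order		elliot/buxton
W21	O2-	H+	HO2	5.0e10	M-1s-1	partially-diffusion-controlled	0.30	elliot/buxton
W22	HO2	HO2	H2O2;O2	8.3e5	M-1s-1	partially-diffusion-controlled	0.40	elliot/buxton
W23	HO2	O2-	HO2-;O2	9.7e7	M-1s-1	partially-diffusion-controlled	0.40	elliot/buxton
W24	HO2-	H+	H2O2	5.0e10	M-1s-1	partially-diffusion-controlled	0.30	elliot/buxton
W25	H	OH-	e-aq	2.2e7	M-1s-1	partially-diffusion-controlled	0.40	elliot/buxton
R1	R	O2	ROO	2.0e9	M-1s-1	background-scavenging		printed
R2	OH	GSH	GS	1.4e10	M-1s-1	background-scavenging		printed
R3	GS	GSH	GSSG-;H+	3.5e8	M-1s-1	background-scavenging		printed
R4	GSSG-	O2	GSSG;O2-	5.1e8	M-1s-1	background-scavenging		printed
C01	OH	RH	R	1.0e8	M-1s-1	background-scavenging		model
C02	H	RH	R;H2	1.0e7	M-1s-1	background-scavenging		model
C03	H	GSH	GS;H2	1.0e9	M-1s-1	background-scavenging		literature
C04	R	GSH	RH;GS	1.0e7	M-1s-1	background-scavenging		literature
C05	R	AH-	RH;A-	1.0e7	M-1s-1	background-scavenging		literature
C06	OH	AH-	A-	1.1e10	M-1s-1	background-scavenging		literature
C07	GS	AH-	GSH;A-	6.0e8	M-1s-1	background-scavenging		literature
C08	OH	TOH	TO	3.8e9	M-1s-1	background-scavenging		literature
C09	ROO	AH-	ROOH;A-	1.0e6	M-1s-1	background-scavenging		literature
C10	TO	AH-	TOH;A-	3.0e5	M-1s-1	background-scavenging		literature
C11	O2-	NO	ONOO-	1.9e10	M-1s-1	background-scavenging		literature
C12	R	NO	RNO	2.0e9	M-1s-1	background-scavenging		literature
C13	R	R	RR	1.0e9	M-1s-1	fully-diffusion-controlled		model
C14	GS	GS	GSSG	1.5e9	M-1s-1	fully-diffusion-controlled		literature
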