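# structalert default substructure-key catalog, v1.
# Curated toxicophore-like SMARTS, one per line, optional tab-separated label.
# Key order is part of the catalog identity: do not reorder or insert.
[N+](=O)[O-]	aromatic_or_aliphatic_nitro
N=O	nitroso
N=[N+]=[N-]	azide
N=N	azo
NN	hydrazine
N=C=O	isocyanate
N=C=S	isothiocyanate
C1OC1	epoxide
C1NC1	aziridine
[CX3H1]=O	aldehyde
C(=O)Cl	acyl_chloride
C(=O)O[CH3]	methyl_ester
C=CC=O	michael_acceptor_enal
C=CC(=O)N	acrylamide
C=CS(=O)(=O)	vinyl_sulfone
[CH2X4][Cl,Br,I]	primary_alkyl_halide
OC[Cl,Br,I]	halohydrin
Nc1ccccc1	aromatic_amine
Oc1ccccc1	phenol
Sc1ccccc1	thiophenol
O=C1C=CC(=O)C=C1	para_quinone
c1ccc2ccccc2c1	naphthalene_core
c1ccc2c(c1)cccn2	quinoline_core
c1ccsc1	thiophene
c1ccoc1	furan
c1cc[nH]c1	pyrrole
[SH]	thiol
S(=O)(=O)N	sulfonamide
C(F)(F)F	trifluoromethyl
OO	peroxide
C#N	nitrile
C(=S)N	thioamide
c1ccccc1	benzene_ring
CN(C)C	tertiary_dimethylamine
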