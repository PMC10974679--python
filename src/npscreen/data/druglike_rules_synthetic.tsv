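# Default drug-likeness/stability rule registry (synthetic stand-in,
# curated in-house): 57 rules in priority order; the messy-rings
# threshold (SSSR > 7) is the pinned literature value.
rule_id	name	predicate	params
messy_rings	Messy rings (SSSR > 7)	max_sssr	{"max": 7}
allowed_elements	Element whitelist (organic subset)	allowed_elements	{"elements": ["C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I"]}
mw_max	Molecular weight <= 900	property_max	{"property": "mw", "max": 900}
heavy_atoms_max	Heavy atoms <= 60	property_max	{"property": "heavy_atoms", "max": 60}
logp_max	Crippen logP <= 7.5	property_max	{"property": "logp", "max": 7.5}
tpsa_max	Topological PSA <= 250	property_max	{"property": "tpsa", "max": 250}
rot_bonds_max	Rotatable bonds <= 12	property_max	{"property": "rot_bonds", "max": 12}
hbd_max	H-bond donors <= 7	property_max	{"property": "hbd", "max": 7}
hba_max	H-bond acceptors <= 12	property_max	{"property": "hba", "max": 12}
neutral	Zero net formal charge	property_max	{"property": "abs_net_charge", "max": 0}
max_ring_size	Largest ring <= 8 atoms	property_max	{"property": "max_ring_size", "max": 8}
aromatic_rings_max	Aromatic rings <= 5	property_max	{"property": "aromatic_rings", "max": 5}
stereocenters_max	Stereocenters <= 4	property_max	{"property": "stereocenters", "max": 4}
halogens_max	Halogen atoms <= 6	smarts_limit	{"smarts": "[F,Cl,Br,I]", "max": 6}
phosphorus_max	Phosphorus atoms <= 1	smarts_limit	{"smarts": "[#15]", "max": 1}
sulfur_max	Sulfur atoms <= 3	smarts_limit	{"smarts": "[#16]", "max": 3}
nitro_max	Nitro groups <= 2	smarts_limit	{"smarts": "[NX3+](=[OX1])[O-]", "max": 2}
aldehyde_max	Aldehydes <= 1	smarts_limit	{"smarts": "[CX3H1]=[OX1]", "max": 1}
thiol_max	Free thiols <= 1	smarts_limit	{"smarts": "[SX2H]", "max": 1}
peroxide	No peroxide (O-O)	smarts_limit	{"smarts": "[OX2][OX2]", "max": 0}
disulfide	No disulfide (S-S)	smarts_limit	{"smarts": "[SX2][SX2]", "max": 0}
n_halogen	No N-halogen bond	smarts_limit	{"smarts": "[#7][F,Cl,Br,I]", "max": 0}
o_halogen	No O-halogen bond	smarts_limit	{"smarts": "[#8][F,Cl,Br,I]", "max": 0}
s_halogen	No S-halogen bond	smarts_limit	{"smarts": "[#16][F,Cl,Br,I]", "max": 0}
acyl_halide	No acyl halide	smarts_limit	{"smarts": "[CX3](=[OX1])[F,Cl,Br,I]", "max": 0}
sulfonyl_halide	No sulfonyl halide	smarts_limit	{"smarts": "[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]", "max": 0}
anhydride	No acid anhydride	smarts_limit	{"smarts": "[CX3](=[OX1])[OX2][CX3](=[OX1])", "max": 0}
isocyanate	No isocyanate	smarts_limit	{"smarts": "[NX2]=[CX2]=[OX1]", "max": 0}
isothiocyanate	No isothiocyanate	smarts_limit	{"smarts": "[NX2]=[CX2]=[SX1]", "max": 0}
ketene	No ketene	smarts_limit	{"smarts": "[CX3]=[CX2]=[OX1]", "max": 0}
allene	No cumulated diene (allene)	smarts_limit	{"smarts": "[CX3]=[CX2]=[CX3]", "max": 0}
azide	No azide	smarts_limit	{"smarts": "[#7-]=[#7+]=[#7]", "max": 0}
diazonium	No diazonium	smarts_limit	{"smarts": "[N+]#N", "max": 0}
azo	No aliphatic azo	smarts_limit	{"smarts": "[#6][NX2]=[NX2][#6]", "max": 0}
hydrazine	No hydrazine (N-N single)	smarts_limit	{"smarts": "[NX3][NX3]", "max": 0}
hydroxylamine	No hydroxylamine (N-OH)	smarts_limit	{"smarts": "[NX3][OX2H]", "max": 0}
n_nitroso	No N-nitroso	smarts_limit	{"smarts": "[NX3][NX2]=[OX1]", "max": 0}
aminal	No aminal (N-C-N sp3)	smarts_limit	{"smarts": "[NX3][CX4][NX3]", "max": 0}
aminol	No hemiaminal (N-C-OH sp3)	smarts_limit	{"smarts": "[NX3][CX4][OX2H]", "max": 0}
hemiacetal	No hemiacetal	smarts_limit	{"smarts": "[OX2H][CX4][OX2]", "max": 0}
orthoester	No orthoester	smarts_limit	{"smarts": "[CX4]([OX2])([OX2])[OX2]", "max": 0}
enol	No enol	smarts_limit	{"smarts": "[OX2H][CX3]=[CX3]", "max": 0}
enamine	No acyclic enamine	smarts_limit	{"smarts": "[NX3][CX3]=[CX3]", "max": 0}
thiocarbonyl	No thiocarbonyl (C=S)	smarts_limit	{"smarts": "[#6]=[SX1]", "max": 0}
aldimine	No aldimine (CH=N)	smarts_limit	{"smarts": "[CX3H1]=[NX2]", "max": 0}
oxime	No oxime	smarts_limit	{"smarts": "[CX3]=[NX2][OX2H]", "max": 0}
epoxide	No epoxide	smarts_limit	{"smarts": "[OX2r3]", "max": 0}
aziridine	No aziridine	smarts_limit	{"smarts": "[NX3r3]", "max": 0}
thiirane	No thiirane	smarts_limit	{"smarts": "[SX2r3]", "max": 0}
michael_acceptor	No acyclic enone (Michael acceptor)	smarts_limit	{"smarts": "[CX3]=[CX3][CX3]=[OX1]", "max": 0}
alpha_halo_carbonyl	No alpha-halo carbonyl	smarts_limit	{"smarts": "[F,Cl,Br,I][CX4][CX3]=[OX1]", "max": 0}
dicarbonyl_12	No 1,2-dicarbonyl	smarts_limit	{"smarts": "[OX1]=[CX3][CX3]=[OX1]", "max": 0}
sulfonate_ester	No sulfonate ester	smarts_limit	{"smarts": "[SX4](=[OX1])(=[OX1])[OX2][#6]", "max": 0}
carbamic_acid	No carbamic acid	smarts_limit	{"smarts": "[NX3][CX3](=[OX1])[OX2H]", "max": 0}
polyether	No triether chain	smarts_limit	{"smarts": "[OX2][CX4][CX4][OX2][CX4][CX4][OX2]", "max": 0}
polyamine	No triamine chain	smarts_limit	{"smarts": "[NX3][CX4][CX4][NX3][CX4][CX4][NX3]", "max": 0}
long_chain	No unbranched C7 aliphatic chain	smarts_limit	{"smarts": "[CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4H2]", "max": 0}
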