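# name: Wimley-White interfacial scale
# units: kcal/mol
# sign_convention: negative = favorable partitioning into the POPC bilayer interface
# citation: Wimley & White, Nat. Struct. Biol. 3:842-848 (1996); D, E, K, R in their charged forms, H neutral
residue,delta_g
A,0.17
C,-0.24
D,1.23
E,2.02
F,-1.13
G,0.01
H,0.17
I,-0.31
K,0.99
L,-0.56
M,-0.23
N,0.42
P,0.45
Q,0.58
R,0.81
S,0.13
T,0.14
V,0.07
W,-1.85
Y,-0.94
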