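# name: Wimley-White octanol scale
# units: kcal/mol
# sign_convention: negative = favorable partitioning into n-octanol (hydrophobic environment)
# citation: Wimley, Creamer & White, Biochemistry 35:5109-5124 (1996); D, E, K, R in their charged forms, H neutral
residue,delta_g
A,0.50
C,-0.02
D,3.64
E,3.63
F,-1.71
G,1.15
H,2.33
I,-1.12
K,2.80
L,-1.25
M,-0.67
N,0.85
P,0.14
Q,0.77
R,1.81
S,0.46
T,0.25
V,-0.46
W,-2.09
Y,-0.71
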