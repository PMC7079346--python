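property	residues
hydrophobic	I,L,V,C,A,G,M,F,Y,W,H,K,T
polar	Y,W,H,K,R,E,Q,D,N,S,T
small	V,C,A,G,D,N,S,T,P
tiny	A,G,S
aliphatic	I,L,V
aromatic	F,Y,W,H
proline	P
positive	H,K,R
negative	D,E
charged	H,K,R,D,E
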