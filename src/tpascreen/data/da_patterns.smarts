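# Donor / acceptor substructure library for push-pull chromophore analysis.
# One pattern per line: SMARTS <whitespace> role (donor|acceptor).
# Donors: electron-rich groups conjugating a lone pair into the pi system.
# Acceptors: electron-poor groups withdrawing density from the pi system.
[NX3;H2;!$(N=*);!$(NC=O);!$(N[!#6;!#1])]	donor
[NX3;H1;!$(N=*);!$(NC=O)]([#6])[#6]	donor
[NX3;H0;!$(N=*);!$(NC=O);!$([N+])]([#6])([#6])[#6]	donor
[OX2H][c]	donor
[OX2;!$(OC=O)]([CX4])[c]	donor
[SX2]([#6])[#6]	donor
[NX3+](=[OX1])[OX1-]	acceptor
[NX3](=[OX1])=[OX1]	acceptor
[CX2]#[NX1]	acceptor
[CX3]=[OX1]	acceptor
[SX4](=[OX1])(=[OX1])	acceptor
[n+]	acceptor
c1sc2ccccc2n1	acceptor
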