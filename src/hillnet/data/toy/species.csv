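# Five-species demonstration network: two input ligands (A, B), receptors
# C and D, output E with a C<->E positive feedback loop gated by !D.
# Blank cells take the documented defaults (tau=1, Ymax=1, y0=0).
name,role,tau,Ymax,y0
A,input,,,
B,input,,,
C,state,,,
D,state,,,
E,state,,,
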