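# Cardiac beta1-adrenergic signaling network: 25 species.
# Inputs: norepinephrine (NE), forskolin (FSK, direct AC activator) and
# IBMX (PDE inhibitor). All species use default parameters
# (tau=1, Ymax=1, y0=0).
name,role,tau,Ymax,y0
NE,input,,,
FSK,input,,,
IBMX,input,,,
B1AR,state,,,
B1ARPG,state,,,
B1ARPA,state,,,
GRK,state,,,
GsaBg,state,,,
GsaGTP,state,,,
GsaGDP,state,,,
Gbg,state,,,
AC,state,,,
cAMP,state,,,
PDE,state,,,
PKI,state,,,
PKAR,state,,,
PKAC,state,,,
PP1,state,,,
PP2A,state,,,
Inhib1,state,,,
PLB,state,,,
TnI,state,,,
IKs,state,,,
ICa,state,,,
RyR,state,,,
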