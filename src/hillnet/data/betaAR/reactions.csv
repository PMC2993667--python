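# Cardiac beta1-adrenergic signaling network: 36 reactions.
# Receptor activation and desensitization, G-protein activation, cAMP/PKA
# axis, phosphatase branch, and five PKA substrates. Rows whose terms are
# all negated (e.g. "!PDE => cAMP") act as multiplicative brakes on the
# target; rows with an empty left side (e.g. "=> PDE") are constitutive
# sources whose weight is the basal drive. The inactive G-protein pool
# GsaBg is constitutively available (weight 1); the negative regulators
# GRK, PDE, PKI, PP1 and PP2A carry a basal drive of 0.2 so they modulate
# rather than saturate their targets (a basal activity of 1 would pin them
# at Ymax, where the inhibiting Hill function vanishes identically and the
# whole cAMP/PKA axis would be shut off).
# Blank weight/n/EC50 cells take the defaults (1, 1.4, 0.5).
id,rule,weight,n,EC50
NE_B1AR,NE => B1AR,,,
B1ARPG_B1AR,!B1ARPG => B1AR,,,
B1ARPA_B1AR,!B1ARPA => B1AR,,,
src_GsaBg,=> GsaBg,1.0,,
B1AR_GsaBg_GsaGTP,B1AR & GsaBg => GsaGTP,,,
B1AR_GsaBg_Gbg,B1AR & GsaBg => Gbg,,,
GsaGTP_GsaGDP,GsaGTP => GsaGDP,,,
GRK_B1ARPG,B1AR & GRK => B1ARPG,,,
PKAC_B1ARPA,B1AR & PKAC => B1ARPA,,,
src_GRK,=> GRK,0.2,,
GsaGTP_AC,GsaGTP => AC,,,
FSK_AC,FSK => AC,,,
AC_cAMP,AC => cAMP,,,
PDE_cAMP,!PDE => cAMP,,,
src_PDE,=> PDE,0.2,,
IBMX_PDE,!IBMX => PDE,,,
cAMP_PKAR,cAMP => PKAR,,,
PKAR_PKAC,PKAR => PKAC,,,
PKI_PKAC,!PKI => PKAC,,,
src_PKI,=> PKI,0.2,,
PKAC_Inhib1,PKAC => Inhib1,,,
PP2A_Inhib1,!PP2A => Inhib1,,,
src_PP1,=> PP1,0.2,,
Inhib1_PP1,!Inhib1 => PP1,,,
src_PP2A,=> PP2A,0.2,,
PKAC_PLB,PKAC => PLB,,,
PP1_PLB,!PP1 => PLB,,,
PP2A_PLB,!PP2A => PLB,,,
PKAC_TnI,PKAC => TnI,,,
PP2A_TnI,!PP2A => TnI,,,
PKAC_IKs,PKAC => IKs,,,
PP2A_IKs,!PP2A => IKs,,,
PKAC_ICa,PKAC => ICa,,,
PP1_ICa,!PP1 => ICa,,,
PKAC_RyR,PKAC => RyR,,,
PP1_RyR,!PP1 => RyR,,,
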