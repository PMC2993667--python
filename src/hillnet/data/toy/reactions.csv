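# Toy network rules; blank weight/n/EC50 cells take defaults (1, 1.4, 0.5).
id,rule,weight,n,EC50
A_C,A => C,,,
E_C,E => C,,,
B_D,B => D,,,
CD_E,C & !D => E,,,
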