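spectrum_id,file_id,frag_mode,charge,adduct
A:scan=10231,A,HCD,3,none
A:scan=10307,A,HCD,4,none
A:scan=10342,A,ETciD,3,none
A:scan=10388,A,ETciD,4,none
A:scan=10415,A,CID,4,none
B:scan=11502,B,HCD,4,none
B:scan=11548,B,EThcD,3,none
B:scan=11590,B,EThcD,4,none
B:scan=11633,B,CID,3,none
B:scan=11710,B,HCD,5,K
B:scan=11754,B,EThcD,5,K
A:scan=10477,A,CID,5,K
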