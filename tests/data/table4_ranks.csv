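comt,httlpr,drd2,frequency_pct,aripiprazole,clozapine,haloperidol,olanzapine,paliperidone,quetiapine,risperidone
MM,LL,A1A1,1.56,3,10,16,16,14,13,12
MM,LL,A1A2,3.13,4,12,16,13,15,10,14
MM,LL,A2A2,1.56,5,12,12,15,13,11,16
MM,Ls,A1A1,3.13,10,8,17,10,14,15,10
MM,Ls,A1A2,6.25,5,11,15,13,17,9,14
MM,Ls,A2A2,3.13,11,9,11,17,14,10,12
MM,ss,A1A1,1.56,17,12,11,8,11,15,10
MM,ss,A1A2,3.13,17,18,6,12,9,13,9
MM,ss,A2A2,1.56,18,15,7,10,12,11,11
MV,LL,A1A1,3.13,5,14,14,15,13,14,9
MV,LL,A1A2,6.25,6,14,13,18,13,9,11
MV,LL,A2A2,3.13,10,14,11,18,11,10,10
MV,Ls,A1A1,6.25,9,10,15,12,11,14,13
MV,Ls,A1A2,12.50,7,7,14,14,16,11,15
MV,Ls,A2A2,6.25,10,9,10,19,12,14,10
MV,ss,A1A1,3.13,16,15,17,14,7,10,5
MV,ss,A1A2,6.25,16,16,14,10,8,13,7
MV,ss,A2A2,3.13,16,13,13,13,10,13,6
VV,LL,A1A1,1.56,7,10,14,10,19,10,14
VV,LL,A1A2,3.13,8,8,13,11,17,9,18
VV,LL,A2A2,1.56,10,10,13,8,15,10,17
VV,Ls,A1A1,3.13,13,11,14,16,8,14,11
VV,Ls,A1A2,6.25,12,4,14,11,14,12,18
VV,Ls,A2A2,3.13,12,9,8,18,11,15,11
VV,ss,A1A1,1.56,16,14,14,4,11,18,7
VV,ss,A1A2,3.13,17,17,9,9,9,15,8
VV,ss,A2A2,1.56,18,13,10,11,11,14,7
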