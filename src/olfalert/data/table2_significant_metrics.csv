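metric,band,channel
ND,delta,Fp1
ND,delta,Fp2
ND,delta,C3
ND,delta,Cz
ND,delta,P8
ND,delta,T4
ND,theta,Fp2
ND,theta,F7
ND,theta,F8
ND,theta,F4
ND,theta,P7
ND,theta,T3
ND,alpha,F3
ND,alpha,C4
ND,beta,Fp1
ND,beta,F4
ND,beta,P8
ND,beta,Pz
ND,beta,P4
ND,gamma,P7
NB,delta,Fp1
NB,delta,Cz
NB,delta,C4
NB,delta,P8
NB,delta,T3
NB,theta,Fp2
NB,theta,F7
NB,alpha,F3
NB,alpha,C4
NB,alpha,P8
NB,alpha,Pz
NB,alpha,O1
NB,beta,Fp1
NB,beta,P8
NB,beta,Pz
NB,beta,P4
NB,gamma,Fp1
NB,gamma,C4
NB,gamma,P7
NE,delta,Fp1
NE,delta,Fp2
NE,delta,F8
NE,delta,C3
NE,delta,Cz
NE,delta,P8
NE,delta,T4
NE,theta,F7
NE,theta,F8
NE,theta,F4
NE,theta,Cz
NE,theta,P7
NE,theta,T3
NE,alpha,F3
NE,beta,Fp1
NE,beta,F4
NE,beta,Pz
NE,beta,P4
NE,gamma,F8
NE,gamma,Pz
NE,gamma,P4
NE,gamma,O2
CC,delta,F7
CC,delta,C3
CC,delta,Pz
CC,delta,P3
CC,theta,Cz
CC,alpha,C3
CC,alpha,P3
CC,beta,Fp2
CC,beta,C3
CC,gamma,F3
PSD,delta,F3
PSD,delta,F8
PSD,delta,P4
PSD,delta,O2
PSD,delta,T4
PSD,theta,F3
PSD,theta,F8
PSD,theta,P4
PSD,theta,O1
PSD,theta,T4
PSD,alpha,Fp1
PSD,alpha,F7
PSD,alpha,F3
PSD,alpha,F8
PSD,alpha,Fz
PSD,alpha,F4
PSD,alpha,C3
PSD,alpha,Pz
PSD,alpha,P4
PSD,alpha,T4
PSD,beta,Fp1
PSD,beta,F7
PSD,beta,F3
PSD,beta,F8
PSD,beta,Fz
PSD,beta,F4
PSD,beta,Cz
PSD,beta,C4
PSD,beta,P4
PSD,gamma,F7
PSD,gamma,F3
PSD,gamma,Fz
PSD,gamma,F4
PSD,gamma,C3
PSD,gamma,Cz
PSD,gamma,C4
PSD,gamma,P3
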