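agonist,treatment,parameter,value,error
C,Co,Emax,89.61,0.03
C,Co,logEC50,-7.53,0.001
C,Co,n,0.75,0.001
C,X,Emax,88.45,0.07
C,X,logEC50,-6.8,0.003
C,X,n,0.76,0.003
C,NB,Emax,70.67,0.12
C,NB,logEC50,-6.66,0.005
C,NB,n,0.91,0.008
C,X+NB,Emax,87.27,0.12
C,X+NB,logEC50,-6.71,0.005
C,X+NB,n,0.82,0.006
A,Co,Emax,89.76,0.01
A,Co,logEC50,-4.92,0.0003
A,Co,n,0.75,0.0004
A,X,Emax,89,0.04
A,X,logEC50,-4.19,0.0008
A,X,n,0.75,0.0007
A,NB,Emax,70.61,0.14
A,NB,logEC50,-5.88,0.005
A,NB,n,0.91,0.009
A,X+NB,Emax,87.27,0.15
A,X+NB,logEC50,-5.93,0.005
A,X+NB,n,0.82,0.006
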