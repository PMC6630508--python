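agonist,treatment,parameter,value,error
C,Co,Emax,89.21,1.46
C,Co,logEC50,-7.47,0.074
C,Co,n,0.98,0.03
C,X,Emax,87.49,1.75
C,X,logEC50,-6.85,0.05
C,X,n,0.93,0.04
C,NB,Emax,71.68,5.24
C,NB,logEC50,-6.53,0.32
C,NB,n,0.84,0.09
C,X+NB,Emax,84.6,1.64
C,X+NB,logEC50,-6.86,0.06
C,X+NB,n,0.86,0.02
A,Co,Emax,91.04,1
A,Co,logEC50,-4.74,0.13
A,Co,n,0.85,0.03
A,X,Emax,93.85,1.78
A,X,logEC50,-3.88,0.07
A,X,n,0.83,0.07
A,NB,Emax,71.23,4.9
A,NB,logEC50,-5.92,0.25
A,NB,n,0.81,0.13
A,X+NB,Emax,90.22,1
A,X+NB,logEC50,-6.08,0.07
A,X+NB,n,0.83,0.1
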