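# IUPAC conventional (abridged) standard atomic weights, 2021 revision
symbol,weight
H,1.008
He,4.0026
Li,6.94
Be,9.0122
B,10.81
C,12.011
N,14.007
O,15.999
F,18.998
Ne,20.180
Na,22.990
Mg,24.305
Al,26.982
Si,28.085
P,30.974
S,32.06
Cl,35.45
Ar,39.95
K,39.098
Ca,40.078
Ti,47.867
Cr,51.996
Mn,54.938
Fe,55.845
Co,58.933
Ni,58.693
Cu,63.546
Zn,65.38
As,74.922
Se,78.971
Br,79.904
Kr,83.798
Rb,85.468
Sr,87.62
Mo,95.95
Ag,107.87
Cd,112.41
Sn,118.71
Sb,121.76
Te,127.60
I,126.904
Xe,131.29
Cs,132.91
Ba,137.33
W,183.84
Pt,195.08
Au,196.97
Hg,200.59
Pb,207.2
Bi,208.98
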