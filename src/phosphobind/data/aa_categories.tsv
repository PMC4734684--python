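aa	category
A	hydrophobic
C	special
D	negative-charged
E	negative-charged
F	hydrophobic
G	special
H	positive-charged
I	hydrophobic
K	positive-charged
L	hydrophobic
M	hydrophobic
N	polar-uncharged
P	special
Q	polar-uncharged
R	positive-charged
S	polar-uncharged
T	polar-uncharged
V	hydrophobic
W	hydrophobic
Y	hydrophobic
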