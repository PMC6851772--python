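# Heavy-metal policy v1: metallic elements with density > 5 g/cm3.
# One element symbol per line; '#' starts a comment. The organic subset
# (H, B, C, N, O, P, S, halogens) and light metals (Li..Al, Ti, Sc, ...)
# are deliberately absent.
V
Cr
Mn
Fe
Co
Ni
Cu
Zn
Ga
Ge
Zr
Nb
Mo
Tc
Ru
Rh
Pd
Ag
Cd
In
Sn
Sb
Hf
Ta
W
Re
Os
Ir
Pt
Au
Hg
Tl
Pb
Bi
# lanthanides
La
Ce
Pr
Nd
Pm
Sm
Eu
Gd
Tb
Dy
Ho
Er
Tm
Yb
Lu
# actinides with measured densities > 5
Ac
Th
Pa
U
Np
Pu
Am
Cm
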