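# Hammett substituent constants (sigma_meta, sigma_para), dimensionless.
# Values from the Hansch-Leo-Taft compilation (Chem. Rev. 1991, 91, 165-195).
# Positive = electron-withdrawing relative to H. Override via --hammett-table.
substituent,sigma_meta,sigma_para
H,0.00,0.00
Me,-0.07,-0.17
Et,-0.07,-0.15
tBu,-0.10,-0.20
Ph,0.06,-0.01
OMe,0.12,-0.27
OH,0.12,-0.37
OCF3,0.38,0.35
NH2,-0.16,-0.66
NMe2,-0.16,-0.83
F,0.34,0.06
Cl,0.37,0.23
Br,0.39,0.23
I,0.35,0.18
CN,0.56,0.66
NO2,0.71,0.78
CF3,0.43,0.54
COMe,0.38,0.50
CO2Me,0.37,0.45
CHO,0.35,0.42
SMe,0.15,0.00
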