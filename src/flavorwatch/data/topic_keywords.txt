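# E-cigarette topic keywords used to pull e-cigarette-related posts from a
# general social-media stream (token-boundary matched, case-insensitive).
e-cig
e-cigs
ecig
ecigs
electroniccigarette
ecigarette
ecigarettes
vape
vapers
vaping
vapes
e-liquid
ejuice
eliquid
e-juice
vapercon
vapeon
vapefam
vapenation
juul
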