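# Keywords flagging promotional accounts: any author handle containing one of
# these as a case-insensitive substring is treated as a vendor/promo account.
dealer
deal
store
supply
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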