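# Reference per-subcategory flavor-mention counts reported for a large-scale
# Reddit e-cigarette flavor surveillance corpus (904,045 flavor-related posts,
# Jan 2013 - Apr 2019). Used by the reference-distribution analysis and as
# printed-count input to the percentage tables.
category	subcategory	count
fruit	berry	727404
fruit	others	374886
fruit	tropical	190639
fruit	melon	138876
fruit	mixed_fruit	102618
fruit	citrus	52503
sweets	dessert	189946
sweets	others	113688
sweets	candy	96866
beverage	coffee	118129
beverage	tea	107449
beverage	milk	21764
beverage	juice	21117
beverage	soft_drink	5377
beverage	others	3169
menthol_or_mint	menthol	173641
menthol_or_mint	mint	56176
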