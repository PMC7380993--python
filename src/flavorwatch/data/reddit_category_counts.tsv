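# Reference per-category flavor-mention counts for the same Reddit corpus as
# reddit_subcategory_counts.tsv.
category	count
fruit	1586926
sweets	400500
beverage	277005
menthol_or_mint	229817
tobacco	163377
others	43922
mixed	24769
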