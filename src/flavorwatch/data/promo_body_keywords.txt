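# Promotion-like body keywords (token-boundary matched): posts containing any
# of these are treated as marketing rather than user feedback.
customer
promotion
discount
sale
free shipping
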