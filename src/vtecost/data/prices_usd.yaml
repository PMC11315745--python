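# United States average prices per examination (statutory insurance), USD.
currency: USD
price_cus: 184
price_ddimer: 14
price_ctpa: 648
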