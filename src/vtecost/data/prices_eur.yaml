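# German medical fee schedule (MFS) tariffs per examination, EUR.
currency: EUR
price_cus: 18.89
price_ddimer: 24.13
price_ctpa: 209.83
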