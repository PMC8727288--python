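{
 "boundaries": [6.80, 7.32, 7.77, 8.28],
 "source": "external_reference",
 "n_reference": 7983,
 "note": "Published quintile boundaries of the 41-SNP CLL polygenic risk score in 7983 European-ancestry consortium controls; printed intervals span [4.32, 11.31). Left-closed right-open bins.",
 "printed_range": [4.32, 11.31]
}
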