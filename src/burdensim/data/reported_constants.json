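{
  "combined_misc_total": 835,
  "discovery_burden_carriers": 12,
  "discovery_burden_cohort_n": 144,
  "discovery_burden_allele_count": 20,
  "discovery_burden_n_variants": 8
}
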