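# Physiological consequences of the three modelled genotypes.
# Half-lives in ms; d2r_scale is a dimensionless striatal D2 expression
# multiplier relative to the heterozygote.
comt_tau_da_cortical_ms:
  VV: 100
  MV: 130
  MM: 160
httlpr_tau_5ht_ms:
  LL: 55
  Ls: 75
  ss: 100
drd2_d2r_scale:
  A1A1: 0.7
  A1A2: 1.0
  A2A2: 1.3
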