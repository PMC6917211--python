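# Ultimate cost-bearer shares by insurance category.
# Rows give the fraction of healthcare spending in each insurance category
# finally borne by households (out-of-pocket and premium shares), the
# government (public programs), and third parties (employers, insurers,
# charity care).  Government shares for the public categories follow
# published payment-flow estimates; the household/third-party split within
# each row is a synthetic default.
shares:
  private:   {household: 0.250, government: 0.050, third_party: 0.700}
  medicare:  {household: 0.150, government: 0.703, third_party: 0.147}
  medicaid:  {household: 0.028, government: 0.952, third_party: 0.020}
  dual:      {household: 0.048, government: 0.932, third_party: 0.020}
  other_gov: {household: 0.150, government: 0.591, third_party: 0.259}
  none:      {household: 0.450, government: 0.100, third_party: 0.450}
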