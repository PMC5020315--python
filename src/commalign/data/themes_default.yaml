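# Default theme configuration: topic groups -> themes.
# The topic -> group section is data-specific and intentionally empty here;
# fill it in for a fitted model (topic id -> group name).
groups:
  media debates: evidence/advocacy
  politics and policy debates: evidence/advocacy
  public health advocacy: evidence/advocacy
  clinical evidence: evidence/advocacy
  scandals and conspiracies: harms/conspiracies
  side effects and harms: harms/conspiracies
  experiences: experiential
topics: {}
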