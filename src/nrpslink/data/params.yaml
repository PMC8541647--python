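# Default scoring parameters. These are documented placeholder values;
# re-learn them from curated alignments with the training module.
level_boundaries:
- 60
- 70
- 80
- 90
- 100
p_a:
  '*': 0.10000000000000098
  aad: 0.015517241379310345
  abu: 0.015517241379310345
  ahp: 0.015517241379310345
  aib: 0.015517241379310345
  ala: 0.015517241379310345
  anth: 0.015517241379310345
  arg: 0.015517241379310345
  asn: 0.015517241379310345
  asp: 0.015517241379310345
  bala: 0.015517241379310345
  bht: 0.015517241379310345
  bmt: 0.015517241379310345
  cap: 0.015517241379310345
  cit: 0.015517241379310345
  cys: 0.015517241379310345
  cysa: 0.015517241379310345
  dab: 0.015517241379310345
  dap: 0.015517241379310345
  dha: 0.015517241379310345
  dhab: 0.015517241379310345
  dhb: 0.015517241379310345
  dhpg: 0.015517241379310345
  dht: 0.015517241379310345
  end: 0.015517241379310345
  fohorn: 0.015517241379310345
  gln: 0.015517241379310345
  glu: 0.015517241379310345
  gly: 0.015517241379310345
  hasn: 0.015517241379310345
  hasp: 0.015517241379310345
  his: 0.015517241379310345
  hiv: 0.015517241379310345
  hleu: 0.015517241379310345
  horn: 0.015517241379310345
  hpg: 0.015517241379310345
  hse: 0.015517241379310345
  hty: 0.015517241379310345
  hyp: 0.015517241379310345
  ile: 0.015517241379310345
  ival: 0.015517241379310345
  kyn: 0.015517241379310345
  lac: 0.015517241379310345
  leu: 0.015517241379310345
  lys: 0.015517241379310345
  met: 0.015517241379310345
  orn: 0.015517241379310345
  phe: 0.015517241379310345
  pheol: 0.015517241379310345
  phg: 0.015517241379310345
  pip: 0.015517241379310345
  pro: 0.015517241379310345
  sal: 0.015517241379310345
  ser: 0.015517241379310345
  thr: 0.015517241379310345
  trp: 0.015517241379310345
  tyr: 0.015517241379310345
  val: 0.015517241379310345
  vol: 0.015517241379310345
p_deletion: 0.05
p_e:
  -1: 0.65
  1: 0.35
p_insertion: 0.05
p_m:
  -1: 0.8
  1: 0.2
p_match_a:
- 0.0
- 0.1
- 0.25
- 0.45
- 0.65
- 0.8
p_match_e:
  -1: 0.5
  1: 0.25
p_match_m:
  -1: 0.55
  1: 0.15
p_mismatch_e:
  -1: 0.15
  1: 0.1
p_mismatch_m:
  -1: 0.2
  1: 0.1
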