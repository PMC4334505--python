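{
 "loop_weights": [
  [
   1.587780265368636,
   -3.063502942306158,
   -3.063502942306158,
   -3.769771739249448
  ],
  [
   -3.769771739249448,
   -3.063502942306158,
   2.2940490623119256,
   -3.769771739249448
  ],
  [
   0.13711885635907065,
   -3.063502942306158,
   0.8433876533023604,
   -0.06933202110835554
  ],
  [
   -1.4478436443620855,
   -0.7415748474187956,
   -3.063502942306158,
   1.2746223801090057
  ]
 ],
 "box_weights": [
  [
   1.0882092558781242,
   -0.7415748474187956,
   -0.2561480202485541,
   -2.184809238528292
  ],
  [
   1.1844245711374275,
   -1.4785404415850019,
   -3.063502942306158,
   -0.5998467378071353
  ],
  [
   -1.4478436443620855,
   -1.4785404415850019,
   -0.2561480202485541,
   1.0882092558781242
  ],
  [
   -0.9624168171918437,
   1.460059013750855,
   -0.2561480202485541,
   -0.9624168171918437
  ],
  [
   -3.769771739249448,
   0.10642205913615425,
   -1.4785404415850019,
   1.1844245711374275
  ],
  [
   -2.184809238528292,
   -3.063502942306158,
   2.065780074638808,
   -1.4478436443620855
  ],
  [
   0.8740844505252771,
   -0.7415748474187956,
   -0.2561480202485541,
   -0.9624168171918437
  ],
  [
   -2.184809238528292,
   -1.4785404415850019,
   -3.063502942306158,
   1.4396816263795023
  ],
  [
   -1.4478436443620855,
   0.10642205913615425,
   1.6913845598573105,
   -2.184809238528292
  ],
  [
   -0.9624168171918437,
   1.460059013750855,
   -0.7415748474187956,
   -0.5998467378071353
  ],
  [
   1.1844245711374275,
   -1.4785404415850019,
   -0.7415748474187956,
   -1.4478436443620855
  ],
  [
   1.0882092558781242,
   -0.7415748474187956,
   -0.2561480202485541,
   -2.184809238528292
  ],
  [
   -2.184809238528292,
   0.10642205913615425,
   -0.7415748474187956,
   0.9851157629140208
  ],
  [
   -2.184809238528292,
   1.8906933680807172,
   -1.4785404415850019,
   -0.9624168171918437
  ],
  [
   -3.769771739249448,
   0.10642205913615425,
   1.460059013750855,
   -0.3103401206121504
  ],
  [
   -0.06933202110835554,
   -1.4785404415850019,
   -0.2561480202485541,
   0.6225456835293127
  ]
 ],
 "pairing_weights": [
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  0.9,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  0.9,
  1.0
 ],
 "component_weights": [
  0.8250000000000001,
  0.17500000000000002,
  0.0
 ],
 "cutoff": 0.85,
 "stem_span": 16,
 "conservation_enabled": false,
 "cleavage_offsets": [
  14,
  15
 ],
 "similarity_refs": [
  "CCGAUUGCAUUAGAACAGAUGUUCUAAUCAAAUCGG",
  "ACGCUUGCAACAGAUUAGAUAAUCUGUUGCAAGCUU",
  "GCGAUUCCAUCCGAUUAGAUAAUCGGAUGGAAUCGC",
  "CCGUUUACAUCACGUGAGAUCACGUGAUGUAAACGG",
  "UCGACUGCACCAUAUUAGAUAAUAUGGUAGAGUCGA",
  "CCUAGUACACCAUAUUAGAUAAUAUGGUGUACUACG",
  "ACGAAUGCAUCAUAUUAGAUAAUAUGAUGCAUUCGU",
  "AACCUUGCUUCACAUUAGGUAAUGUGAAGCAAGGUU",
  "ACGGUGGCAACAGAUUAGGUAAUCUGUUCACACCGU",
  "ACGAUUGCAGCACAACAGGUGUUGUGCUGCAAUCUU",
  "UCGAUAGCAUCGGUUUAGGUAAACCGAUGCUAUCGA",
  "ACAGUAAUAUCGAAGUAGGUACUUCGAUAUUACUGU",
  "ACGAUCUCACCAGCUUAGGUAAGCUGGUUUGAUCGU",
  "UCAGUCGCAUCAGAUUAGGUAAUCUGAUGCGACUCA",
  "UAGACUGCGUCGAUUGAGUUCAAUCGACGCAGUCUA",
  "ACGAGUGCAACAGCACAGUUGUGCUGUUGCACUCGU",
  "UAGAUUACAGAAAAUAAGUAUAUUUUCUCAAAUCUA",
  "ACGAUUGGAUCAGAUUAGUAAAUCUGAUCCAAUCCU",
  "UCGGCUGCAUCGGCUUAGUCAAGCCGAUGCAGCCGA",
  "AGAAUUGCAUAAGAAUAGUCAUUCUUAUGCAAUUCU"
 ],
 "seq_lo": -29.33955028172449,
 "seq_hi": 2.5864805857402473,
 "struct_lo": 0.02347259783310556,
 "struct_hi": 0.5126729407334077,
 "sim_lo": 0.0,
 "sim_hi": 0.1388888888888889,
 "stability_center": -10.0,
 "stability_scale": 3.0,
 "struct_mix": 0.5
}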