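# Morphological atlas: declarative mapping from (region, change) findings to
# disease labels.  Rules fire in descending priority; a rule with `subsumes`
# consumes its required findings so the listed component diseases are not
# co-reported.  region: null means any admissible region.
schema_version: "1"
rules:
  - disease: bpes
    priority: 10
    requires:
      - {region: upper_eyelid, change: ptosis}
      - {region: inner_canthus, change: epicanthus_inversus}
    params:
      - {param: icd_mm, op: lt, value: 30.0}
    subsumes: [blepharoptosis, epicanthus_inversus]
  - disease: blepharoptosis
    requires:
      - {region: upper_eyelid, change: ptosis}
  - disease: tao
    requires:
      - {region: upper_eyelid, change: upper_retraction}
  - disease: tao
    requires:
      - {region: lower_eyelid, change: lower_retraction}
  - disease: ectropion
    requires:
      - {region: lower_eyelid, change: ectropion}
  - disease: entropion_and_trichiasis
    requires:
      - {region: null, change: entropion_trichiasis}
  - disease: eyelid_tumor
    requires:
      - {region: null, change: tumor}
  - disease: epicanthus_inversus
    requires:
      - {region: inner_canthus, change: epicanthus_inversus}
  - disease: epicanthus_other
    requires:
      - {region: inner_canthus, change: epicanthus_other}
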