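# Packaged supporting-knowledge rules.
#
# The diplotype -> phenotype-class tables below are ILLUSTRATIVE: they cover
# the worked examples (e.g. CYP2C9 *2/*3 -> poor metabolizer) plus a few
# plausible companions, and are NOT clinically authoritative.  Institutions
# should replace them with curated diplotype-to-phenotype tables.
format_version: 1
rules:
  - sk_id: cyp2c9-pm-2-2
    if:
      - {fact: genotype, args: [CYP2C9, "*2/*2"]}
    derived: {fact: phenotype_class, args: [CYP2C9, poor_metabolizer]}
  - sk_id: cyp2c9-pm-2-3
    if:
      - {fact: genotype, args: [CYP2C9, "*2/*3"]}
    derived: {fact: phenotype_class, args: [CYP2C9, poor_metabolizer]}
  - sk_id: cyp2c9-pm-3-3
    if:
      - {fact: genotype, args: [CYP2C9, "*3/*3"]}
    derived: {fact: phenotype_class, args: [CYP2C9, poor_metabolizer]}
  - sk_id: cyp2c19-pm-2-2
    if:
      - {fact: genotype, args: [CYP2C19, "*2/*2"]}
    derived: {fact: phenotype_class, args: [CYP2C19, poor_metabolizer]}
  - sk_id: cyp2c19-pm-2-3
    if:
      - {fact: genotype, args: [CYP2C19, "*2/*3"]}
    derived: {fact: phenotype_class, args: [CYP2C19, poor_metabolizer]}
  - sk_id: cyp2c19-pm-3-3
    if:
      - {fact: genotype, args: [CYP2C19, "*3/*3"]}
    derived: {fact: phenotype_class, args: [CYP2C19, poor_metabolizer]}
  - sk_id: cyp2d6-pm-3-4
    if:
      - {fact: genotype, args: [CYP2D6, "*3/*4"]}
    derived: {fact: phenotype_class, args: [CYP2D6, poor_metabolizer]}
  - sk_id: cyp2d6-pm-4-4
    if:
      - {fact: genotype, args: [CYP2D6, "*4/*4"]}
    derived: {fact: phenotype_class, args: [CYP2D6, poor_metabolizer]}
  - sk_id: cyp2d6-pm-4-5
    if:
      - {fact: genotype, args: [CYP2D6, "*4/*5"]}
    derived: {fact: phenotype_class, args: [CYP2D6, poor_metabolizer]}
  - sk_id: cyp2d6-pm-5-5
    if:
      - {fact: genotype, args: [CYP2D6, "*5/*5"]}
    derived: {fact: phenotype_class, args: [CYP2D6, poor_metabolizer]}
  - sk_id: age-child
    if:
      - {fact: age, args: ["?a"]}
      - {guard: {var: a, op: "<", value: 18}}
    derived: {fact: demographic_class, args: [child]}
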