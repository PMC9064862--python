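# Keyword/size rules for lasso peptide gene classification.
# Size windows generalize sizes observed across characterized clusters
# (B1 ~276-303 bp, B2 ~375-471 bp, C ~1863-1929 bp, D ~810-822 bp) with
# margins; matching is case-insensitive regex over description and domain tag.
labels:
  B2:
    domain_patterns: ["PF13471"]
    desc_patterns: ["lasso peptide biosynthesis B2"]
    size_bp: [300, 600]
  B1:
    domain_patterns: ["PF05402"]
    desc_patterns: ["PqqD"]
    size_bp: [150, 400]
  C:
    domain_patterns: ["Asn_synthase"]
    desc_patterns: ["asparagine synth"]
    size_bp: [1500, 2200]
  D:
    domain_patterns: ["ABC transporter"]
    desc_patterns: ["ABC transporter (permease|ATP-binding)"]
    size_bp: [600, 1200]
  A:
    domain_patterns: ["predicted lasso peptide"]
    desc_patterns: []
    size_bp: [1, 210]
    allow_precursor_scan: true
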