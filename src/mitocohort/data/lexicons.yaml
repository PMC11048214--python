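# Default label lexicons for pathogenicity-predictor simplification.
# Matching is case-insensitive; spaces, hyphens and underscores are
# interchangeable. Labels outside both lists simplify to NA.
deleterious:
  - possibly damaging
  - probably damaging
  - deleterious
  - pathogenic
  - medium deleterious
  - high deleterious
benign:
  - tolerated
  - benign
  - neutral
  - likely benign
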