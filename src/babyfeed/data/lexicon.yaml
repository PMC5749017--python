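# Default feeding-search lexicon for well-baby EMR notes.
# All phrases are matched case-insensitively with flexible whitespace and
# word-boundary anchoring. User configs may override any category, but every
# category key must be present and non-empty.
rourke_variants:
  - rourke baby record
  - rourke
  - well baby visit
  - well baby check up
  - well baby check
  - well child visit
  - newborn visit
  - 1 month visit
  - 2 month visit
  - 4 month visit
  - 6 month visit
breast_terms:
  - breastfeeding
  - breast feeding
  - breastfed
  - breast fed
  - breast milk
  - breast
  - nursing
  - bf
  - ebf
formula_terms:
  - formula
  - formula fed
  - bottle fed formula
  - similac
  - enfamil
mixed_markers:
  - both breast and formula
  - supplementing
  - supplementation
  - breast and formula
  - mixed feeding
exclusivity_markers:
  - exclusively
  - exclusive
  - only
negation_markers:
  - "no"
  - not
  - stopped
  - weaned
  - discontinued
  - denies
# Duration-bearing historical statements: each pattern is a regular
# expression with named groups <num> and <unit>.
historical_patterns:
  - '(?:was|previously|prev)\s+(?:exclusively\s+)?breast\s?(?:fed|feeding)\s+(?:until|for|x)\s+(?P<num>\d+(?:\.\d+)?)\s*(?P<unit>months?|mos?|weeks?|wks?|days?)\b'
  - '(?:exclusively\s+)?breast\s?(?:fed|feeding)\s+(?:until|for|x)\s+(?P<num>\d+(?:\.\d+)?)\s*(?P<unit>months?|mos?|weeks?|wks?|days?)\b'
  - 'ebf\s+(?:until|for|x)\s+(?P<num>\d+(?:\.\d+)?)\s*(?P<unit>months?|mos?|weeks?|wks?|days?)\b'
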