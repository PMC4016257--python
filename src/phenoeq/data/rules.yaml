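# Quality replacement rules.
#
# Unconditional rules always fire: curated EQ statements write "absent"
# (PATO:0000462) as "lacks all parts of type" (PATO:0002000).
#
# Conditional rules fire only when the token pattern (at most one "*" gap
# wildcard) occurs in the phenotype label.  The "decreased" mirrors of the
# "increased" rules ship with the trigger only; supply a replacement id to
# activate them.
unconditional:
  - trigger: PATO:0000462       # absent
    replacement: PATO:0002000   # lacks all parts of type
conditional:
  - pattern: "increased activity"
    trigger: PATO:0000470       # increased
    replacement: PATO:0000912   # increased rate
  - pattern: "increased * number"
    trigger: PATO:0000470
    replacement: PATO:0002001   # has extra parts of type
  - pattern: "decreased activity"
    trigger: PATO:0001997       # decreased
    replacement: null
  - pattern: "decreased * number"
    trigger: PATO:0001997
    replacement: null
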