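# Contrasts for the demo cohort. Group keys are "condition|crosslinked|ligand".
contrasts:
  - name: "ENG/NRP1 crosslink"
    kind: crosslink
    free: "NRP1+ENG|no|none"
    crosslinked: "NRP1+ENG|yes|none"
  - name: "ENG/VEGFR2 crosslink"
    kind: crosslink
    free: "VEGFR2+ENG|no|none"
    crosslinked: "VEGFR2+ENG|yes|none"
  - name: "VEGFR2/NRP1 crosslink"
    kind: crosslink
    free: "NRP1+VEGFR2|no|none"
    crosslinked: "NRP1+VEGFR2|yes|none"
  - name: "VEGFR2/NRP1 crosslink + ENG coexpression"
    kind: crosslink
    strict: false        # arms differ in coexpressed (untagged) partner
    free: "NRP1+VEGFR2|no|none"
    crosslinked: "NRP1+VEGFR2+ENG|yes|none"
  - name: "VEGF-A effect on crosslinked ENG/NRP1"
    kind: ligand
    base: "NRP1+ENG|yes|none"
    plus_ligand: "NRP1+ENG|yes|VEGF-A"
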