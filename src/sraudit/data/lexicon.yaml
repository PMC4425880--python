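# Controlled keyword lists used to probe free-text metadata fields for
# annotation of the three library-preparation protocol steps, plus the
# reagent-kit keywords. A trailing/leading '%' marks a fuzzy-match stem;
# matching strips '%' and tests for a case-insensitive substring.
fragmentation:
  - shear
  - restriction
  - digest
  - fragment
  - breaks
  - acoustic
  - nebulisation
  - nebulization
  - nebuliz
  - nebulis
  - sonic
adapter_ligation:
  - adapter
  - "ligat%"
  - "blunt%"
  - "phosphorylat%"
  - overhang
  - t4-pnk
  - t4
  - pnk
  - kinase
  - a-tail
  - "anneal%"
  - "denature%"
enrichment:
  - "clone%"
  - "clonin%"
  - "vector%"
  - pcr
  - "amplif%"
  - polymerase
  - taq
  - phusion
  - "temperat%"
  - "thermal%"
reagent:
  - reagent
  - kit
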