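# Three-locus background-change (cryptic epistasis) scenario:
# island adaptation A, continental adaptation B with a strong DMI,
# background allele C fixed in both demes.
preset: cryptic_deleterious_B
dynamics:
  m: 0.5
  continental_hap: aBC
  mode: loose
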