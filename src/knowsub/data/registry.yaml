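# Module manifest: files are loaded in order, so later modules may reuse
# the questions and decisions declared by earlier ones.
modules:
  - persistence.kb
  - bioaccumulation.kb
  - toxicity.kb
  - pbt.kb
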