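# Bundled haplotype motif table: B4a1a1 sub-haplotype markers plus the
# classic Polynesian motif.
#
# "!" entries are active reference-state assertions (the sample must carry
# the rCRS allele there); plain entries are required derived states.
# Note: the Polynesian motif is variously described as the 9-bp deletion
# plus three control-region substitutions or plus four (16189C, 16217C,
# 16247G, 16261T); this table includes all four and the deletion.
motifs:
  B4a1a1c:
    parent: B4a1a1
    requires: ["1185!", "4769G", "14022G", "16126C", "16189C", "16217C", "16247!", "16261T"]
  B4a1a1a:
    parent: B4a1a1
    requires: ["1185!", "4769G", "14022G", "16126!", "16189C", "16217C", "16247G", "16261T"]
  B4a1a1a3:
    parent: B4a1a1a
    requires: ["1185T", "4769!", "14022G", "16126!", "16189C", "16217C", "16247G", "16261T"]
  B4a1a1a5:
    parent: B4a1a1a
    requires: ["1185!", "4769G", "14022G", "16126C", "16189C", "16217C", "16247G", "16261T"]
  Polynesian-motif:
    requires: ["8281-8289d", "16189C", "16217C", "16247G", "16261T"]
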