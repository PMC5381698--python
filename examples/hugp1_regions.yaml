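# Functional regions of human UDP-glucose pyrophosphorylase, long-isoform
# (hUGP1) author numbering.  The short isoform (hUGP2, e.g. the apo
# structure 3R2W) lacks the 11 N-terminal residues: apply offset +11 when
# resolving these regions on a short-isoform chain.
SB-loop:
  ranges: [[286, 293]]   # sugar-binding loop, T286-G293
  scheme: hUGP1
SB-region:
  ranges: [[282, 327]]   # V282-F327: SB-loop plus flanking strands/helices
  scheme: hUGP1
interlock-partner:
  ranges: [[456, 456]]   # D456 at the base of the C-terminal beta-helix
  scheme: hUGP1
beta23:
  ranges: [[501, 508]]   # C-terminal strand mediating end-to-end dimers
  scheme: hUGP1
catalytic-core:
  ranges: [[130, 280]]   # stable catalytic-domain stretch used as fit frame
  scheme: hUGP1
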