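# Signed synteny-block orders of the focal distal-Xq locus in the two
# Y-less spiny-rat species, as encoded by this package from published
# synteny maps of the genus.  SB1-SB4 are X-derived blocks (ancestrally
# SB1+ SB2+ SB3+ SB4+, anchored by conserved flanking sequence); SB5 and
# SB6 are the Y-derived insertion; SB5p is the duplicated partial copy of
# SB5 (SB5') and is excluded before any distance computation.
#
# The published maps carry the orders graphically, not as text; this file
# is the package's reading of them and users may substitute their own.
arrangements:
  osimensis: "SB1+ SB6- SB5p- SB2+ SB5+ SB3+ SB4+"
  tokunoshimensis: "SB1+ SB5p+ SB5- SB2+ SB3+ SB6+ SB4+"
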