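# Default hypervariable-region primer panel for 16S rRNA coverage profiling.
# Canonical broad-range primers; positions follow E. coli numbering in the
# primer names.  Matching tolerance and amplicon bounds live here too, so a
# profiling run is fully reproducible from this file.
max_mismatch: 2
min_amplicon: 50
max_amplicon: 2000
pairs:
  - region: V1-V2
    forward_name: 27F
    forward: AGAGTTTGATCMTGGCTCAG
    reverse_name: 338R
    reverse: TGCTGCCTCCCGTAGGAGT
  - region: V1-V3
    forward_name: 27F
    forward: AGAGTTTGATCMTGGCTCAG
    reverse_name: 534R
    reverse: ATTACCGCGGCTGCTGG
  - region: V3
    forward_name: 341F
    forward: CCTACGGGNGGCWGCAG
    reverse_name: 534R
    reverse: ATTACCGCGGCTGCTGG
  - region: V4
    forward_name: 515F
    forward: GTGYCAGCMGCCGCGGTAA
    reverse_name: 806R
    reverse: GGACTACNVGGGTWTCTAAT
  - region: V3-V4
    forward_name: 341F
    forward: CCTACGGGNGGCWGCAG
    reverse_name: 805R
    reverse: GACTACHVGGGTATCTAATCC
  - region: V3-V5
    forward_name: 341F
    forward: CCTACGGGNGGCWGCAG
    reverse_name: 926R
    reverse: CCGYCAATTYMTTTRAGTTT
  - region: V4-V5
    forward_name: 515F
    forward: GTGYCAGCMGCCGCGGTAA
    reverse_name: 926R
    reverse: CCGYCAATTYMTTTRAGTTT
  - region: V6-V8
    forward_name: 926F
    forward: AAACTYAAAKGAATTGACGG
    reverse_name: 1392R
    reverse: ACGGGCGGTGTGTRC
  - region: V6-V9
    forward_name: 926F
    forward: AAACTYAAAKGAATTGACGG
    reverse_name: 1492R
    reverse: TACGGYTACCTTGTTACGACTT
  - region: V7-V9
    forward_name: 1115F
    forward: CAACGAGCGCAACCC
    reverse_name: 1492R
    reverse: TACGGYTACCTTGTTACGACTT
  - region: V1-V9
    forward_name: 27F
    forward: AGAGTTTGATCMTGGCTCAG
    reverse_name: 1492R
    reverse: TACGGYTACCTTGTTACGACTT
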