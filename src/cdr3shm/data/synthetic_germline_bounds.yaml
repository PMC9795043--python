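# Region boundary sidecar for the packaged synthetic germline database.
# All intervals are 0-based half-open nucleotide coordinates on the segment.
# V segments: FR1..FR3 intervals; the sequence 3' of fr3 is the
# junction-contributing tail (here the A-R codons after the conserved C104,
# which is the last FR3 codon).
# J segments: fr4_start is the offset of the conserved FR4 tryptophan codon.
# D segments: reading_frames lists usable frames (1-based: frame f means
# translation of the segment starts at nucleotide f-1).
IGHV-CLAN1-SYN:
  class: V
  fr1: [0, 45]
  cdr1: [45, 69]
  fr2: [69, 114]
  cdr2: [114, 138]
  fr3: [138, 198]
IGHV1-69-SYN:
  class: V
  fr1: [0, 45]
  cdr1: [45, 69]
  fr2: [69, 114]
  cdr2: [114, 138]
  fr3: [138, 198]
IGHD6-19-SYN:
  class: D
  reading_frames: [1]
IGHD3-16-SYN:
  class: D
  reading_frames: [2]
IGHJ4-SYN:
  class: J
  fr4_start: 9
IGHJ3-SYN:
  class: J
  fr4_start: 12
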