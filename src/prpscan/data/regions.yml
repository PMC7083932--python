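# Default bait-region coordinates, 1-based inclusive.
#
# The PZP / A2ML1 entries are in the human-vs-marmoset pairwise ALIGNMENT
# frame: lengths and region boundaries reproduce the published region-length
# denominators (protein: 682/56/753 for PZP and 542/44/724 for A2ML1;
# nucleotide: codon-consistent 168 = 3x56 and 132 = 3x44 bait windows; the
# nucleotide totals include non-coding mRNA stretches).  Exact per-sequence
# bait coordinates were never published; override this file to supply them.
sequences:
  - {id: PZP_protein_alignment,   length: 1491, bait_start: 683,  bait_end: 738}
  - {id: A2ML1_protein_alignment, length: 1310, bait_start: 543,  bait_end: 586}
  - {id: PZP_mrna_alignment,      length: 4612, bait_start: 2079, bait_end: 2246}
  - {id: A2ML1_mrna_alignment,    length: 5040, bait_start: 2003, bait_end: 2134}
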