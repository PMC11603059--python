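"""Parse a RepeatMasker table and reduce it to one entry per TE locus.

Builds a tiny annotation table with two overlapping LTR hits and a simple
repeat, then applies the redundancy filter (drop non-TEs, keep the best-scoring
entry per overlap cluster, require match length > 80 bp).
"""

from tescope import filter_redundancy, parse_rm_out

RM_OUT = """\
463 1.3 0.6 1.7 contig_1 101 600 (400) + ERV1-1 LTR/ERV1 1 500 (0) 1
251 8.2 0.0 0.3 contig_1 451 700 (300) + Gypsy-2 LTR/Gypsy 1 250 (0) 2
 38 2.0 0.0 0.0 contig_1 801 860 (140) + (TA)n Simple_repeat 1 60 (0) 3
312 5.5 0.1 0.0 contig_2 1 420 (80) C L2-1 LINE/L2 (0) 420 1 4
"""

annotations = parse_rm_out(RM_OUT)
filtered = filter_redundancy(annotations, min_length=80)

print(f"parsed {len(annotations)} entries, {len(filtered)} survive filtering")
for ann in filtered:
    cls = ann.classification
    print(f"  {ann.contig_id}:{ann.start}-{ann.end}  {ann.repeat_name:8s} "
          f"score={ann.sw_score}  class={cls.te_class}")

# The ERV1 hit (score 463) beats the overlapping Gypsy hit (score 251); the
# simple repeat is not a TE and is dropped; the LINE entry stands alone.
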