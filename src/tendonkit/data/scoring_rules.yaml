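# Quantitative band boundaries of the histomorphometric scoring rubric.
# Boundary inclusivity conventions:
#   cellularity: score 3 = fold change < 1.3; score 2 = [1.3, 2];
#                score 1 = (2, 3]; score 0 = > 3  (exact 3 scores 1)
#   alignment:   score 0 = ratio > 3; score 1 = (2.1, 3];
#                score 3 = ratio < 1 with dispersion < 25%;
#                score 2 = everything else (ratio <= 2.1)
version: '1'
cellularity_bounds: [1.3, 2.0, 3.0]
alignment_bounds: [1.0, 2.1, 3.0]
dispersion_percent: 25.0
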