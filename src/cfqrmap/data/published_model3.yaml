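# Published domain-level mapping functions (Model 3: screened CFQ-R domains
# plus screened squared terms), recommended for estimating EQ-5D-3L utilities
# from CFQ-R domain scores when no utility data were collected.
#
# Domain scores enter on their native 0-100 scale, uncentred; squared terms
# are the plain squares of the same scores.  Coefficients are reproduced at
# full printed precision together with their bootstrapped (bias-corrected,
# 2000 replications) standard errors.  The part-1 intercept of the two-part
# model was not published; it is recorded explicitly as unavailable (null),
# never as zero, and the two-part applicator refuses to run without a
# user-supplied or refit value.
provenance: >
  Domain-level mapping coefficients as published for the UK adult
  cystic-fibrosis survey (n=401) from which these functions were estimated.
ols_model3:
  coefficients:
    physical:    0.00651
    role:        0.00287
    emotion:     0.00693
    vitality:    0.00127
    eat:         0.00154
    weight:     -0.00058
    digest:      0.00094
    physical_sq: -0.00004
    emotion_sq:  -0.00004
    const:      -0.09898
  se:
    physical:    0.00141
    role:        0.00057
    emotion:     0.00211
    vitality:    0.00062
    eat:         0.00053
    weight:      0.00028
    digest:      0.00044
    physical_sq: 0.00001
    emotion_sq:  0.00002
    const:       0.06297
tpm_model3_part1:
  coefficients:
    physical: 0.02836
    role:     0.03285
    emotion:  0.04287
    const:    null        # not published
  se:
    physical: 0.00834
    role:     0.01221
    emotion:  0.01020
tpm_model3_part2:
  coefficients:
    physical:    0.00615
    role:        0.00336
    emotion:     0.00821
    vitality:    0.00592
    eat:         0.00206
    weight:     -0.00090
    digest:      0.00106
    physical_sq: -0.00004
    vitality_sq: -0.00005
    emotion_sq:  -0.00006
    const:      -0.22122
  se:
    physical:    0.00188
    role:        0.00075
    emotion:     0.00277
    vitality:    0.00257
    eat:         0.00067
    weight:      0.00040
    digest:      0.00061
    physical_sq: 0.00002
    vitality_sq: 0.00003
    emotion_sq:  0.00003
    const:       0.07169
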