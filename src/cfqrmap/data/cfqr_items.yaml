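# Default CFQ-R (teen/adult, 50-item) item map: domain membership,
# reverse-coding flags and special-item markers.
#
# The instrument's developer distributes the authoritative item->domain map
# and reverse-coding list with its scoring manual; this file is a complete,
# editable stand-in with the instrument's domain structure (item counts per
# domain) and a declared-assumption reverse-coding list.  The synthetic
# cohort generator and the test suite use this same map, so scoring and
# generation are always mutually consistent.  Users with the licensed manual
# can point the scorer at their own copy of this file.
#
# reverse: true  ->  raw response 1 is the *best* level; recode r -> 5 - r so
#                    that, after recoding, 4 always means best health.
# sub_question: item 43 is a conditional sub-question not answered by all
#                    respondents and is excluded from modelling.
domains:
  physical:    {label: "Physical functioning"}
  role:        {label: "Role functioning"}
  vitality:    {label: "Vitality"}
  emotion:     {label: "Emotional functioning"}
  social:      {label: "Social functioning"}
  body:        {label: "Body image"}
  eat:         {label: "Eating disturbance"}
  treat:       {label: "Treatment burden"}
  health:      {label: "Health perceptions"}
  weight:      {label: "Weight"}
  respiratory: {label: "Respiratory symptoms"}
  digest:      {label: "Digestive symptoms"}
items:
  1:  {domain: physical}
  2:  {domain: physical}
  3:  {domain: physical}
  4:  {domain: physical}
  5:  {domain: physical, reverse: true}
  6:  {domain: physical, reverse: true}
  7:  {domain: physical}
  8:  {domain: physical}
  9:  {domain: role}
  10: {domain: role}
  11: {domain: role}
  12: {domain: role}
  13: {domain: vitality, reverse: true}
  14: {domain: vitality}
  15: {domain: vitality, reverse: true}
  16: {domain: vitality}
  17: {domain: emotion, reverse: true}
  18: {domain: emotion, reverse: true}
  19: {domain: emotion}
  20: {domain: emotion, reverse: true}
  21: {domain: emotion}
  22: {domain: social}
  23: {domain: social}
  24: {domain: social}
  25: {domain: social}
  26: {domain: social}
  27: {domain: social}
  28: {domain: body, reverse: true}
  29: {domain: body, reverse: true}
  30: {domain: body}
  31: {domain: eat, reverse: true}
  32: {domain: eat, reverse: true}
  33: {domain: eat}
  34: {domain: treat, reverse: true}
  35: {domain: treat, reverse: true}
  36: {domain: treat}
  37: {domain: health}
  38: {domain: health}
  39: {domain: health}
  40: {domain: weight, reverse: true}
  41: {domain: respiratory, reverse: true}
  42: {domain: respiratory, reverse: true}
  43: {domain: respiratory, reverse: true, sub_question: true,
       label: "How has your mucus been?"}
  44: {domain: respiratory, reverse: true}
  45: {domain: respiratory, reverse: true}
  46: {domain: respiratory}
  47: {domain: respiratory}
  48: {domain: digest, reverse: true}
  49: {domain: digest, reverse: true}
  50: {domain: digest, reverse: true}
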