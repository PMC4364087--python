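# UK general-population EQ-5D-3L value set (time trade-off, Dolan).
# Utility = 1 minus the decrements below.  `constant` applies once for any
# move away from full health (11111); `n3` applies once if any dimension is
# at level 3.  Scoring spans [-0.594, 1.0]; the loader validates both anchors.
id: uk_tto
name: UK TTO value set (general population)
full_health: 1.0
constant: 0.081
n3: 0.269
decrements:
  mobility:            {2: 0.069, 3: 0.314}
  self_care:           {2: 0.104, 3: 0.214}
  usual_activity:      {2: 0.036, 3: 0.094}
  pain_discomfort:     {2: 0.123, 3: 0.386}
  anxiety_depression:  {2: 0.071, 3: 0.236}
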