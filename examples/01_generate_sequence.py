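"""Generate a constrained trial sequence and check it against the rules.

A default toddler block has 32 trials: 24 with the target in the frequent
(prepotent) location and 8 in the rare (inhibitory) location, starting with a
3-trial prepotent lead-in and with at most 5 prepotent / 2 inhibitory trials
in a row.  Sampling is exactly uniform over the valid arrangements.
"""

from ecitt import BlockConfig, Counterbalance, generate_sequence, validate_sequence
from ecitt.session_io import sequence_frame

config = BlockConfig.ecitt()
cb = Counterbalance("P001", prepotent_location="top")
seq = generate_sequence(config, cb, seed=7)

frame = sequence_frame(seq)
print(frame.head(10).to_string(index=False))
print(f"...\n{len(seq)} trials, "
      f"{sum(s.condition == 'inhibitory' for s in seq)} inhibitory, "
      f"violations: {validate_sequence(seq, config)}")
# The empty violation list confirms the counts, lead-in and run caps all hold.
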