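"""Generate a roving oddball tone sequence and summarize its structure.

Each block repeats one tone (400-800 Hz, 50 Hz grid) 3-11 times; the first
tone of a block is a deviant that becomes the new standard on repetition.
"""
import numpy as np
from mmn_dcm import generate_roving_sequence

seq = generate_roving_sequence(n_blocks=200, seed=1)
lengths = np.bincount(seq.block_index)
print(f"trials: {seq.n_trials}, blocks: {len(lengths)}")
print(f"block length mean {lengths.mean():.2f} (uniform 3..11 has mean 7), "
      f"range {lengths.min()}..{lengths.max()}")
counts = {lab: seq.condition_label.count(lab)
          for lab in ("deviant", "rep1", "rep5", "surplus")}
print("condition counts:", counts)
# every deviant is the first tone of its block, with a frequency change
freqs = seq.tone_frequency_hz
dev = seq.repetition_index == 0
print("all block-initial tones are deviants:",
      bool(np.all(np.array(seq.condition_label)[dev] == "deviant")))
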