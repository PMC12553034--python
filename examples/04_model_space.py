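"""Enumerate the 12-model space of parieto-frontal architectures.

Six architectures (parietal attachment and expectancy input) crossed with
two repetition bases: exponential decay (E) or exponential plus phasic
change (EG).  Prints each model's fronto-parietal edges, inputs and number
of free parameters.
"""
import numpy as np
from mmn_dcm import enumerate_model_space, default_priors

models = enumerate_model_space()
print(f"{len(models)} models\n")
for m in models:
    rn = m.region_names
    edges = [f"{rn[s]}->{rn[d]}"
             for d in range(len(rn)) for s in range(len(rn))
             if m.fwd_mask[d, s] and {rn[s][:3], rn[d][:3]} == {"IFG", "IPC"}]
    exp = [rn[i] for i in m.expectancy_input]
    nfree = int(default_priors(m).free_mask.sum())
    desc = ", ".join(edges) if edges else "none"
    print(f"model {m.model_id:3s}: fronto-parietal {desc:34s} "
          f"expectancy->{'+'.join(exp)}  free params {nfree}")
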