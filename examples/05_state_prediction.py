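"""Exact binary symptom-state probability from six sign forecasts.

The state is 1 when itching + sleep disturbance >= 2 and at least two of
redness, dryness, oedema, oozing are non-zero.  Treating the six forecasts
as independent, the induced state probability factorizes exactly; the
brute-force sum over all 15,625 joint outcomes confirms it.
"""

import numpy as np

import adforecast as af

rng = np.random.default_rng(5)
forecasts = {s: rng.dirichlet(np.ones(5)) for s in af.SIGNS}
p_fast = af.state_probability(forecasts)
p_brute = af.state_probability_bruteforce(forecasts)
print(f"factorized: {p_fast:.12f}")
print(f"brute force: {p_brute:.12f}  (agree to {abs(p_fast - p_brute):.1e})")

realized = {s: 2 for s in af.SIGNS}
outcome = af.derive_symptom_state(realized)
print(f"realized state for all-2 scores: {outcome}; Brier = {af.brier(p_fast, outcome):.4f}")
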