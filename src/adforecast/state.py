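"""Binary AD symptom-state probability from six per-sign forecasts.

The symptom state is 1 when itching + sleep disturbance >= 2 and at least
two of redness, dryness, oedema, oozing are non-zero.  Treating the six
sign forecasts as independent random variables, the state probability
factorizes exactly as P(A) * P(B): condition A involves only itching and
sleep (handled by discrete convolution), condition B only the other four
signs (a Poisson-binomial tail over their non-zero probabilities) — the two
sign sets are disjoint.

A brute-force enumeration over all 5^6 joint outcomes is provided as an
independent oracle.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .panel import SIGNS, derive_symptom_state

_PMF_TOL = 1e-6


def _check_pmf(pmf, name):
    pmf = np.asarray(pmf, dtype=float)
    if pmf.shape != (5,):
        raise ValueError(f"forecast for {name!r} must have 5 probabilities")
    if np.any(pmf < -1e-12) or abs(pmf.sum() - 1.0) > _PMF_TOL:
        raise ValueError(f"forecast for {name!r} is not a valid pmf: {pmf}")
    return np.clip(pmf, 0.0, 1.0)


def state_probability(forecasts: Mapping[str, np.ndarray]) -> float:
    """Exact induced probability that the symptom state equals 1.

    ``forecasts`` maps each of the six sign names to a 5-category pmf.
    """
    pmf = {s: _check_pmf(forecasts[s], s) for s in SIGNS}
    # A: itching + sleep >= 2, by convolution of the two pmfs
    conv = np.convolve(pmf["itching"], pmf["sleep"])
    p_a = float(conv[2:].sum())
    # B: >= 2 of the four skin signs non-zero (Poisson-binomial tail)
    q = [1.0 - p[0] for p in (pmf["redness"], pmf["dryness"], pmf["oedema"], pmf["oozing"])]
    tail = np.zeros(5)
    tail[0] = 1.0
    for qi in q:  # tail is the count pmf, built by sequential convolution
        tail[1:] = tail[1:] * (1 - qi) + tail[:-1] * qi
        tail[0] *= 1 - qi
    p_b = float(tail[2:].sum())
    return min(max(p_a * p_b, 0.0), 1.0)


_STATE_MASK = None


def _state_mask():
    """Boolean table over all 5^6 score combinations, cached."""
    global _STATE_MASK
    if _STATE_MASK is None:
        grids = np.meshgrid(*[np.arange(5)] * 6, indexing="ij")
        scores = {s: g for s, g in zip(SIGNS, grids)}
        a = scores["itching"] + scores["sleep"] >= 2
        b = sum((scores[s] > 0).astype(int) for s in ("redness", "dryness", "oedema", "oozing")) >= 2
        _STATE_MASK = a & b
    return _STATE_MASK


def state_probability_bruteforce(forecasts: Mapping[str, np.ndarray]) -> float:
    """Oracle: sum the joint product probability over all 15,625 outcomes."""
    pmf = [_check_pmf(forecasts[s], s) for s in SIGNS]
    joint = np.einsum("a,b,c,d,e,f->abcdef", *pmf)
    return float(joint[_state_mask()].sum())
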