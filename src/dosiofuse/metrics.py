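"""Concordance metrics for right-censored survival data."""

from __future__ import annotations

import numpy as np

__all__ = ["harrell_cindex", "somers_dxy"]


def harrell_cindex(risk, time, event) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable iff the smaller observed time carries an
    event; it is concordant if the shorter-lived subject has the higher risk
    score; tied risk scores count 1/2.

    Returns C in [0, 1]; 0.5 is random, 1 perfect.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(risk) == len(time) == len(event)):
        raise ValueError("risk, time and event must have equal length")
    # pair (i, j): comparable if t_i < t_j and e_i = 1 (i fails first)
    ti, tj = time[:, None], time[None, :]
    ri, rj = risk[:, None], risk[None, :]
    ei = event[:, None]
    comparable = (ti < tj) & (ei == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (need at least one event before another time)")
    concordant = int((comparable & (ri > rj)).sum())
    tied = int((comparable & (ri == rj)).sum())
    return (concordant + 0.5 * tied) / n_comp


def somers_dxy(risk, time, event) -> float:
    """Somers' Dxy rank correlation: ``Dxy = 2 * (C - 0.5)``."""
    return 2.0 * (harrell_cindex(risk, time, event) - 0.5)
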