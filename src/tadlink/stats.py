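"""Small shared statistical helpers."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "mc_p_value"]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot FDR-adjust an empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mc_p_value(n_at_least_as_extreme: int, n_total: int) -> float:
    """Monte Carlo p-value with the (r + 1) / (n + 1) bias correction.

    Never returns 0: the observed statistic counts as one realization of
    its own null.
    """
    return (n_at_least_as_extreme + 1) / (n_total + 1)
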