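"""Fisher-information analysis for experimental design.

The observable per particle is the binary state S ~ Ber(q) with
q = 1 - (1 - p*f_l)^n_sat, so the per-particle Fisher information about
the binding probability p is the Bernoulli information under
reparameterisation,

    I(p) = (dq/dp)^2 / (q (1 - q)),    dq/dp = n_sat * f_l * (1 - p*f_l)^(n_sat - 1).

Information from V independent particles is V * I(p).  Low inverse
information 1/(V*I) marks designs (f_l, V) that estimate p precisely for a
hypothesised n_sat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import prob_positive

__all__ = [
    "DesignPoint",
    "fisher_information",
    "dq_dp",
    "inverse_information_landscape",
]


@dataclass(frozen=True)
class DesignPoint:
    """A candidate design: rare-label fraction and hypothesised complex size,
    evaluated at an assumed binding probability; V scales information linearly."""

    f_l: float
    n_sat: int
    p: float
    V: int | None = None


def dq_dp(p: float, f_l: float, n_sat: int):
    """Sensitivity of the positive-state probability to p (analytic)."""
    p = np.asarray(p, dtype=float)
    f_l = np.asarray(f_l, dtype=float)
    n = np.asarray(n_sat, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        # (1-p f_l)^(n-1) in log space for numerical range
        log_pow = (n - 1.0) * np.log1p(-p * f_l)
    out = n * f_l * np.exp(log_pow)
    if np.ndim(out) == 0:
        return float(out)
    return out


def fisher_information(p: float, f_l: float, n_sat: int):
    """Per-particle Fisher information about p for design (f_l, n_sat).

    Raises for degenerate designs where q is 0 or 1 (a particle whose state
    is certain carries no information about p).
    """
    p_arr = np.asarray(p, dtype=float)
    f_arr = np.asarray(f_l, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("p must be strictly inside (0, 1)")
    if np.any((f_arr <= 0) | (f_arr > 1)):
        raise ValueError("f_l must be in (0, 1]")
    n_arr = np.asarray(n_sat)
    if np.any(n_arr < 1):
        raise ValueError("n_sat must be >= 1")
    q = prob_positive(p, f_l, n_sat)
    q_arr = np.asarray(q, dtype=float)
    if np.any((q_arr <= 0.0) | (q_arr >= 1.0)):
        raise ValueError("design is uninformative: q is degenerate (0 or 1)")
    out = np.asarray(dq_dp(p, f_l, n_sat)) ** 2 / (q_arr * (1.0 - q_arr))
    if np.ndim(out) == 0:
        return float(out)
    return out


def inverse_information_landscape(
    f_l_grid: Sequence[float],
    n_sat_grid: Sequence[int],
    p: float = 0.5,
    V: int = 1000,
) -> pd.DataFrame:
    """Inverse Fisher information 1/(V*I) over an (f_l, n_sat) design grid.

    Low values mark designs that pin down p precisely.  Degenerate cells
    (q numerically 0 or 1) are recorded as +inf, never dropped.  Returns a
    long-format DataFrame with columns f_l, n_sat, p, V, inverse_information.
    """
    if len(f_l_grid) == 0 or len(n_sat_grid) == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for n in n_sat_grid:
        for f in f_l_grid:
            try:
                info = fisher_information(p, f, int(n)) * V
                inv = 1.0 / info if info > 0 else np.inf
            except ValueError:
                inv = np.inf
            rows.append((float(f), int(n), float(p), int(V), inv))
    return pd.DataFrame(
        rows, columns=["f_l", "n_sat", "p", "V", "inverse_information"]
    )
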