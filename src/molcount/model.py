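"""Core probability model for binary differential labelling.

A complex binds ``K ~ Bin(n_sat, p)`` labelled molecules, of which a
``Bin(K, f_l)`` subset carries the rare B label.  The observable is the
Bernoulli state ``S = 1(at least one B-labelled molecule bound)`` with
success probability ``q``.  Marginalising K gives the closed form

    q = 1 - (1 - p * f_l) ** n_sat

which is the only place model parameters meet the data: a scored sample
(V particles, V_plus positive) contributes a Bernoulli likelihood
``q**V_plus * (1-q)**(V-V_plus)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExperimentCondition",
    "BinaryScoreSet",
    "ModelParams",
    "prob_positive",
    "log_likelihood",
    "expected_count",
]


@dataclass(frozen=True)
class ExperimentCondition:
    """Experimental condition of one scored sample.

    Parameters
    ----------
    f_l
        Fraction of the component pool carrying the rare B label, in (0, 1].
    concentration
        Antibody concentration label in µg/ml.  Metadata only; it never
        enters the likelihood.
    sample_id
        Opaque identifier, unique within a dataset.
    """

    f_l: float
    concentration: float = float("nan")
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.f_l <= 1.0):
            raise ValueError(f"f_l must be in (0, 1], got {self.f_l}")


@dataclass(frozen=True)
class BinaryScoreSet:
    """Binary outcome summary of one sample: V particles scored, V_plus positive.

    Only the sufficient statistic ``V_plus`` is stored; per-particle state
    vectors carry no extra likelihood information.
    """

    condition: ExperimentCondition
    V: int
    V_plus: int

    def __post_init__(self) -> None:
        if self.V < 1:
            raise ValueError(f"V must be >= 1, got {self.V}")
        if not (0 <= self.V_plus <= self.V):
            raise ValueError(f"V_plus must be in [0, V], got {self.V_plus} with V={self.V}")


@dataclass
class ModelParams:
    """The unknowns of the joint model: one binding probability per sample
    plus a single saturation count shared across all samples."""

    p_values: list[float] = field(default_factory=list)
    n_sat: int = 1

    def __post_init__(self) -> None:
        for p in self.p_values:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"binding probability out of [0, 1]: {p}")
        if int(self.n_sat) != self.n_sat or self.n_sat < 0:
            raise ValueError(f"n_sat must be a non-negative integer, got {self.n_sat}")


def _validate_unit(name: str, x) -> None:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError(f"{name} must lie in [0, 1]")


def prob_positive(p, f_l, n_sat):
    """Probability ``q`` that a complex carries at least one rare-label molecule.

    Computes ``q = 1 - (1 - p*f_l)**n_sat`` in log space
    (``-expm1(n_sat * log1p(-p*f_l))``) so large ``n_sat`` cannot underflow.
    The equivalent explicit sum over the binomial occupancy distribution is
    kept only as a test oracle.

    Accepts scalars or broadcastable arrays; returns a float for scalar input.
    """
    _validate_unit("p", p)
    _validate_unit("f_l", f_l)
    n = np.asarray(n_sat)
    if not np.issubdtype(n.dtype, np.integer):
        nf = np.asarray(n_sat, dtype=float)
        if np.any(nf != np.floor(nf)):
            raise ValueError("n_sat must be integer-valued")
        n = nf
    if np.any(n < 0):
        raise ValueError("n_sat must be non-negative")

    pf = np.asarray(p, dtype=float) * np.asarray(f_l, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_neg = n * np.log1p(-pf)  # log P(S=0); -inf when pf==1, nan when 0*inf
    log_neg = np.where((pf == 1.0) & (n == 0), 0.0, log_neg)
    q = -np.expm1(log_neg)
    q = np.clip(q, 0.0, 1.0)
    if np.ndim(q) == 0:
        return float(q)
    return q


def expected_count(p: float, n_sat: int) -> float:
    """Expected number of bound molecules per complex, ``E[K] = n_sat * p``."""
    _validate_unit("p", p)
    if n_sat < 0 or int(n_sat) != n_sat:
        raise ValueError(f"n_sat must be a non-negative integer, got {n_sat}")
    return float(n_sat) * float(p)


def bernoulli_log_likelihood(V, V_plus, q):
    """Log of ``q**V_plus * (1-q)**(V-V_plus)`` with 0*log(0) := 0.

    Returns -inf when the data are impossible under ``q`` (positives seen at
    q=0, or negatives seen at q=1).  Vectorised over broadcastable inputs.
    """
    V = np.asarray(V, dtype=float)
    Vp = np.asarray(V_plus, dtype=float)
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = np.where(Vp > 0, Vp * np.log(q), 0.0)
        neg = np.where(V - Vp > 0, (V - Vp) * np.log1p(-q), 0.0)
    out = pos + neg
    out = np.where(np.isnan(out), -np.inf, out)
    if np.ndim(out) == 0:
        return float(out)
    return out


def log_likelihood(scores: Sequence[BinaryScoreSet], params: ModelParams) -> float:
    """Joint log-likelihood of binary-score data under the model.

    Each sample j contributes
    ``V_plus_j * ln(q_j) + (V_j - V_plus_j) * ln(1 - q_j)`` with
    ``q_j = prob_positive(p_j, f_l_j, n_sat)``; samples multiply because
    particles (and experiments) are assumed independent.
    """
    if len(params.p_values) != len(scores):
        raise ValueError(
            f"got {len(params.p_values)} p values for {len(scores)} score sets"
        )
    total = 0.0
    for score, p in zip(scores, params.p_values):
        q = prob_positive(p, score.condition.f_l, params.n_sat)
        ll = bernoulli_log_likelihood(score.V, score.V_plus, q)
        if not math.isfinite(ll):
            return -math.inf
        total += ll
    return total
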