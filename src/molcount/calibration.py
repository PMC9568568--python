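"""Intensity calibration and population-heterogeneity analysis.

The model's stoichiometric estimate for a sample (expected molecules per
complex) anchors a linear conversion from A-channel fluorescence to
per-particle molecule counts: the median intensity is matched to the
estimate, and every particle's intensity is scaled by the same factor.
The resulting count distributions are summarised with a log-normal fit
(fluorescence populations are right-skewed under multiplicative noise)
and mean counts across a titration with a one-site binding curve
``n(c) = n_max * c / (K_half + c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .model import BinaryScoreSet, ExperimentCondition

__all__ = [
    "ParticleRecord",
    "CalibratedSample",
    "calibrate",
    "fit_lognormal",
    "binding_curve_fit",
    "score_binary",
]


@dataclass(frozen=True)
class ParticleRecord:
    """One particle's fluorescence record.

    ``b_positive`` is the binary rare-label call; raw B intensities are
    thresholded upstream by :func:`score_binary`.
    """

    sample_id: str
    particle_id: str
    ref_intensity: float
    a_intensity: float
    b_positive: int

    def __post_init__(self) -> None:
        if self.ref_intensity < 0 or self.a_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.b_positive not in (0, 1):
            raise ValueError(f"b_positive must be 0 or 1, got {self.b_positive}")


@dataclass
class CalibratedSample:
    """Per-particle inferred counts for one sample plus the fitted log-normal
    heterogeneity summary."""

    sample_id: str
    scale: float  # molecules per intensity unit
    counts: np.ndarray
    lognormal_mu: float = float("nan")
    lognormal_sigma: float = float("nan")
    lognormal_r2: float = float("nan")
    n_excluded: int = 0

    @property
    def max_count(self) -> float:
        return float(np.max(self.counts))


def calibrate(
    records: Sequence[ParticleRecord], stoich_estimate: float
) -> CalibratedSample:
    """Convert A-channel intensities to molecule counts via the median anchor.

    ``scale = stoich_estimate / median(a_intensity)``; by construction the
    median inferred count equals the model's estimate for the sample.  The
    conversion is scale-equivariant: rescaling all intensities by a common
    factor leaves the counts unchanged.
    """
    if len(records) < 10:
        raise ValueError(f"need >= 10 particles to calibrate, got {len(records)}")
    if stoich_estimate <= 0:
        raise ValueError("stoich_estimate must be positive")
    a = np.array([r.a_intensity for r in records], dtype=float)
    med = float(np.median(a))
    if med <= 0:
        raise ValueError("degenerate sample: median A intensity is not positive")
    scale = stoich_estimate / med
    sample_id = records[0].sample_id
    return CalibratedSample(sample_id=sample_id, scale=scale, counts=a * scale)


def fit_lognormal(counts: np.ndarray, n_bins: int | None = None):
    """Maximum-likelihood log-normal fit to inferred counts.

    Non-positive counts are excluded (their number is reported on the
    result); the fit is on the log scale, ``mu = mean(log x)``,
    ``sigma = std(log x)``.  Goodness is the R^2 of the fitted density
    against a density-normalised histogram (Freedman-Diaconis bins unless
    ``n_bins`` is given) — reported for comparability with least-squares
    fits of binned frequencies, but the parameters themselves are
    bin-independent.

    Returns ``(mu, sigma, r2, n_excluded)``.
    """
    counts = np.asarray(counts, dtype=float)
    positive = counts[counts > 0]
    n_excluded = int(counts.size - positive.size)
    if positive.size < 10:
        raise ValueError(f"need >= 10 positive counts, got {positive.size}")
    log_x = np.log(positive)
    mu = float(log_x.mean())
    sigma = float(log_x.std(ddof=0))  # MLE
    if sigma == 0.0:
        raise ValueError("degenerate counts: zero spread on the log scale")
    if n_bins is None:
        edges = np.histogram_bin_edges(positive, bins="fd")
    else:
        edges = np.histogram_bin_edges(positive, bins=n_bins)
    density, edges = np.histogram(positive, bins=edges, density=True)
    mids = 0.5 * (edges[:-1] + edges[1:])
    fitted = stats.lognorm.pdf(mids, s=sigma, scale=np.exp(mu))
    ss_res = float(np.sum((density - fitted) ** 2))
    ss_tot = float(np.sum((density - density.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return mu, sigma, r2, n_excluded


def binding_curve_fit(
    concentrations: Sequence[float], mean_counts: Sequence[float]
):
    """One-site binding (Langmuir) fit of mean counts against concentration.

    Least squares on ``n(c) = n_max * c / (K_half + c)``.  Returns
    ``(n_max, K_half, r2)``.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(mean_counts, dtype=float)
    if c.size < 3:
        raise ValueError(f"need >= 3 concentration points, got {c.size}")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")

    def hyperbola(c, n_max, k_half):
        return n_max * c / (k_half + c)

    p0 = (float(y.max()) or 1.0, float(np.median(c)))
    try:
        popt, _ = optimize.curve_fit(
            hyperbola, c, y, p0=p0, bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"binding curve fit did not converge: {err}") from err
    resid = y - hyperbola(c, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(popt[0]), float(popt[1]), r2


def score_binary(
    records: Sequence[ParticleRecord] | Sequence[tuple],
    b_threshold: float | None = None,
    b_values: Sequence[float] | None = None,
    condition: ExperimentCondition | None = None,
) -> BinaryScoreSet:
    """Aggregate per-particle rare-label calls into a binary score set.

    With ``b_values`` given, raw B-channel intensities are thresholded at
    ``b_threshold`` (value >= threshold scores positive); otherwise the
    records' existing ``b_positive`` flags are counted.
    """
    V = len(records)
    if V < 1:
        raise ValueError("need at least one particle")
    if b_values is not None:
        if b_threshold is None or b_threshold <= 0:
            raise ValueError("b_threshold must be positive when thresholding intensities")
        flags = np.asarray(b_values, dtype=float) >= b_threshold
        if flags.size != V:
            raise ValueError("b_values length must match records")
        V_plus = int(flags.sum())
    else:
        V_plus = int(sum(r.b_positive for r in records))
    cond = condition or ExperimentCondition(
        f_l=1.0, sample_id=getattr(records[0], "sample_id", "")
    )
    return BinaryScoreSet(condition=cond, V=V, V_plus=V_plus)
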