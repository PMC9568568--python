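"""Generative simulator for binary-labelling experiments.

Produces both table shapes the analysis consumes — aggregated binary
scores and per-particle fluorescence records — with exactly the
statistical structure the model assumes: occupancy K ~ Bin(n_sat, p),
rare-label count B ~ Bin(K, f_l), positive state 1(B >= 1), and A-channel
intensity proportional to the A-labelled occupancy with multiplicative
log-normal noise.  Marginally the positive fraction must agree with the
closed form q = 1 - (1 - p*f_l)^n_sat; that agreement is the key
consistency check between simulator and model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import ParticleRecord
from .model import BinaryScoreSet, ExperimentCondition

__all__ = [
    "GeneratorConfig",
    "TitrationDataset",
    "generate_particles",
    "particles_to_score_set",
    "generate_titration",
    "generate_study",
]

# reference-channel population: fixed log-normal, arbitrary units
_REF_LOG_MEAN = np.log(1000.0)
_REF_LOG_SD = 0.2


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of one simulated sample.

    ``intensity_gain`` is fluorescence units per A-labelled molecule;
    ``intensity_cv`` the coefficient of variation of the multiplicative
    measurement noise (0.1 = 10%, a typical single-particle TIRF value).
    """

    n_sat: int = 133
    f_l: float = 0.01
    p: float = 0.5
    V: int = 2000
    intensity_gain: float = 10.0
    intensity_cv: float = 0.1
    seed: int = 0
    sample_id: str = "sim"
    concentration: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_sat < 0 or int(self.n_sat) != self.n_sat:
            raise ValueError("n_sat must be a non-negative integer")
        if not (0.0 <= self.f_l <= 1.0):
            raise ValueError("f_l must be in [0, 1]")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be in [0, 1]")
        if self.V < 1:
            raise ValueError("V must be >= 1")
        if self.intensity_gain <= 0:
            raise ValueError("intensity_gain must be positive")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be non-negative")


@dataclass
class TitrationDataset:
    """A multi-concentration simulated experiment: aggregated scores plus
    the per-particle records they were derived from."""

    scores: list[BinaryScoreSet]
    particles: list[ParticleRecord]
    p_true: list[float]
    n_sat: int


def _noise_sigma(cv: float) -> float:
    # log-normal with E[exp(eps)] CV = cv  =>  sigma^2 = ln(1 + cv^2)
    return float(np.sqrt(np.log1p(cv * cv)))


def generate_particles(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[ParticleRecord]:
    """Simulate per-particle records under the hierarchical generative model.

    Per particle: total occupancy ``K ~ Bin(n_sat, p)``; rare-label count
    ``B ~ Bin(K, f_l)``; ``b_positive = 1(B >= 1)``; A intensity
    ``gain * (K - B) * exp(eps)`` with log-normal multiplicative noise at
    the requested CV (A intensity tracks the A-labelled molecules only; at
    operating f_l <= 0.07 this differs from total occupancy by <= 7%).
    Deterministic given the config seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    K = rng.binomial(config.n_sat, config.p, size=config.V)
    B = rng.binomial(K, config.f_l)
    sigma = _noise_sigma(config.intensity_cv)
    eps = rng.normal(0.0, sigma, size=config.V) if sigma > 0 else np.zeros(config.V)
    a = config.intensity_gain * (K - B) * np.exp(eps)
    ref = rng.lognormal(_REF_LOG_MEAN, _REF_LOG_SD, size=config.V)
    return [
        ParticleRecord(
            sample_id=config.sample_id,
            particle_id=f"{config.sample_id}-{i:06d}",
            ref_intensity=float(ref[i]),
            a_intensity=float(a[i]),
            b_positive=int(B[i] >= 1),
        )
        for i in range(config.V)
    ]


def particles_to_score_set(
    records: Sequence[ParticleRecord], f_l: float, concentration: float = float("nan")
) -> BinaryScoreSet:
    """Aggregate generated records into the sufficient-statistic table row."""
    return BinaryScoreSet(
        condition=ExperimentCondition(
            f_l=f_l,
            concentration=concentration,
            sample_id=records[0].sample_id,
        ),
        V=len(records),
        V_plus=int(sum(r.b_positive for r in records)),
    )


def generate_titration(
    concentrations: Sequence[float],
    K_half: float = 1.0,
    n_sat: int = 133,
    f_l: float | Sequence[float] = 0.01,
    V: int | Sequence[int] = 2000,
    intensity_gain: float = 10.0,
    intensity_cv: float = 0.1,
    seed: int = 0,
    sample_prefix: str = "s",
) -> TitrationDataset:
    """Simulate a titration: one sample per antibody concentration.

    Occupancy rises with concentration through the one-site (Langmuir)
    mapping ``p(c) = c / (c + K_half)`` — a generative convenience for test
    realism; the inference model itself never uses concentration.  ``f_l``
    and ``V`` may be scalars or per-sample sequences.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0 or np.any(conc <= 0):
        raise ValueError("concentrations must be positive and non-empty")
    if K_half <= 0:
        raise ValueError("K_half must be positive")
    m = conc.size
    f_l_arr = np.broadcast_to(np.asarray(f_l, dtype=float), (m,))
    V_arr = np.broadcast_to(np.asarray(V, dtype=int), (m,))

    scores: list[BinaryScoreSet] = []
    particles: list[ParticleRecord] = []
    p_true: list[float] = []
    for j, c in enumerate(conc):
        p_j = float(c / (c + K_half))
        cfg = GeneratorConfig(
            n_sat=n_sat,
            f_l=float(f_l_arr[j]),
            p=p_j,
            V=int(V_arr[j]),
            intensity_gain=intensity_gain,
            intensity_cv=intensity_cv,
            seed=seed + j,
            sample_id=f"{sample_prefix}{j:02d}",
            concentration=float(c),
        )
        recs = generate_particles(cfg)
        particles.extend(recs)
        scores.append(particles_to_score_set(recs, cfg.f_l, cfg.concentration))
        p_true.append(p_j)
    return TitrationDataset(scores=scores, particles=particles, p_true=p_true, n_sat=n_sat)


def generate_study(
    n_sat: int = 133,
    concentrations: Sequence[float] = (0.15, 0.6, 2.5, 5.0, 10.0, 20.0),
    f_l_per_titration: Sequence[float] = (0.007, 0.015, 0.03, 0.07),
    V: int = 1500,
    K_half: float = 1.0,
    seed: int = 0,
) -> list[BinaryScoreSet]:
    """Synthetic multi-titration study: several independent titrations over
    the same concentration range, each with its own rare-label fraction.

    Defaults emulate a realistic four-titration design (24 samples, label
    fractions 0.7-7%, ~1500 particles per sample, concentrations spanning
    a >100-fold range across the saturation point).  Synthetic data: every
    score is drawn from the hierarchical generative model, so the true
    saturation count is known exactly.  Returns the aggregated score sets
    only; use :func:`generate_titration` when per-particle records are
    needed too.
    """
    scores: list[BinaryScoreSet] = []
    for t, f_l in enumerate(f_l_per_titration):
        ds = generate_titration(
            concentrations,
            K_half=K_half,
            n_sat=n_sat,
            f_l=float(f_l),
            V=V,
            seed=seed + 1000 * t,
            sample_prefix=f"t{t}s",
        )
        scores.extend(ds.scores)
    return scores
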