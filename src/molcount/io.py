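"""CSV readers/writers with validation, and posterior/result serialisation.

Two pinned table formats (comma-delimited, '.' decimal, UTF-8, '\\n' line
endings):

* binary scores — ``sample_id,concentration_ug_ml,f_l,n_particles,n_positive``
* particle records — ``sample_id,particle_id,ref_intensity,a_intensity,b_value``
  where ``b_value`` is either a {0,1} positivity flag or a raw B-channel
  intensity to be thresholded downstream.

Malformed rows are rejected with messages naming the offending row number
(1-based, counting the header as line 1).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import ParticleRecord
from .inference import PosteriorResult
from .model import BinaryScoreSet, ExperimentCondition

__all__ = [
    "SCORES_COLUMNS",
    "PARTICLES_COLUMNS",
    "ValidationError",
    "read_scores",
    "write_scores",
    "read_particles",
    "write_particles",
    "write_posterior",
    "write_draws",
    "write_table",
    "file_sha256",
]

logger = logging.getLogger("molcount")

SCORES_COLUMNS = ["sample_id", "concentration_ug_ml", "f_l", "n_particles", "n_positive"]
PARTICLES_COLUMNS = ["sample_id", "particle_id", "ref_intensity", "a_intensity", "b_value"]


class ValidationError(ValueError):
    """Input table violates the pinned schema or a domain invariant."""


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing} (expected {expected})")


def read_scores(path) -> list[BinaryScoreSet]:
    """Read a binary-score table; empty data section yields an empty list."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, SCORES_COLUMNS, path)
    if df.empty:
        logger.warning("%s: header only, no score rows", path)
        return []
    scores = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        sid = str(row["sample_id"])
        if sid in seen:
            raise ValidationError(f"{path} row {line}: duplicate sample_id {sid!r}")
        seen.add(sid)
        f_l = float(row["f_l"])
        if not (0.0 < f_l <= 1.0):
            raise ValidationError(f"{path} row {line}: f_l={f_l} outside (0, 1]")
        V = int(row["n_particles"])
        V_plus = int(row["n_positive"])
        if V < 1:
            raise ValidationError(f"{path} row {line}: n_particles={V} must be >= 1")
        if not (0 <= V_plus <= V):
            raise ValidationError(
                f"{path} row {line}: n_positive={V_plus} outside [0, n_particles={V}]"
            )
        scores.append(
            BinaryScoreSet(
                condition=ExperimentCondition(
                    f_l=f_l,
                    concentration=float(row["concentration_ug_ml"]),
                    sample_id=sid,
                ),
                V=V,
                V_plus=V_plus,
            )
        )
    return scores


def write_scores(scores: Sequence[BinaryScoreSet], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.condition.sample_id for s in scores],
            "concentration_ug_ml": [s.condition.concentration for s in scores],
            "f_l": [np.format_float_positional(s.condition.f_l, trim="-") for s in scores],
            "n_particles": [s.V for s in scores],
            "n_positive": [s.V_plus for s in scores],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_particles(path, b_threshold: float | None = None) -> list[ParticleRecord]:
    """Read a particle table.

    If ``b_threshold`` is given, ``b_value`` is treated as a raw B-channel
    intensity and thresholded (>= threshold scores positive); otherwise it
    must already be a {0,1} flag.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, PARTICLES_COLUMNS, path)
    if df.empty:
        logger.warning("%s: header only, no particle rows", path)
        return []
    records = []
    for idx, row in df.iterrows():
        line = idx + 2
        ref = float(row["ref_intensity"])
        a = float(row["a_intensity"])
        if ref < 0 or a < 0:
            raise ValidationError(f"{path} row {line}: negative intensity")
        b = float(row["b_value"])
        if b_threshold is not None:
            flag = int(b >= b_threshold)
        else:
            if b not in (0.0, 1.0):
                raise ValidationError(
                    f"{path} row {line}: b_value={b} is not a 0/1 flag "
                    "(pass a threshold to score raw intensities)"
                )
            flag = int(b)
        records.append(
            ParticleRecord(
                sample_id=str(row["sample_id"]),
                particle_id=str(row["particle_id"]),
                ref_intensity=ref,
                a_intensity=a,
                b_positive=flag,
            )
        )
    return records


def write_particles(records: Sequence[ParticleRecord], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "particle_id": [r.particle_id for r in records],
            "ref_intensity": [repr(r.ref_intensity) for r in records],
            "a_intensity": [repr(r.a_intensity) for r in records],
            "b_value": [r.b_positive for r in records],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def write_posterior(
    result: PosteriorResult, path, provenance: dict | None = None
) -> None:
    """Serialise posterior summaries (MAP, CI, R-hat, acceptance) to JSON."""
    payload = {
        "parameters": {
            name: {
                "map": result.map[name],
                "ci95": list(result.ci[name]),
                "rhat": result.rhat[name],
                "lag1_autocorr": result.autocorr[name],
            }
            for name in result.draws
        },
        "accept_rates": result.accept_rates,
        "converged": result.converged(),
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_draws(result: PosteriorResult, path) -> None:
    """Raw draws in long format: parameter,chain,iteration,value."""
    frames = []
    for name, arr in result.draws.items():
        n_chains, n_draws = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "parameter": name,
                    "chain": np.repeat(np.arange(n_chains), n_draws),
                    "iteration": np.tile(np.arange(n_draws), n_chains),
                    "value": arr.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, lineterminator="\n")


def write_table(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False, lineterminator="\n")


def file_sha256(path) -> str:
    """Checksum used in run logs so any output can be traced to its inputs."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
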