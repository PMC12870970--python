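"""Synthetic beta-bounded methylation aging trajectories with known labels.

Fifteen trajectory archetypes cover the patterns the classifier is meant to
separate: a flat non-correlated baseline, linear increase/decrease, convex
quadratic trends, logarithmic transitions, sigmoidal switches with inflection
points at ages 25, 40 and 80 (both directions), an age-dependent
variance-increasing profile, and a non-monotonic mid-life bump.

For every archetype except VI, the age-specific expectation mu(age) is drawn
through a Beta distribution with precision ``phi`` (mean mu, variance
mu(1-mu)/(1+phi)), which keeps values in [0, 1] with realistic
mean-dependent noise; phi = 100 gives an SD of about 0.05 at mu = 0.5. The
VI archetype adds Gaussian noise to a flat 0.5 mean with the SD rising
linearly from 0.01 before age 25 to 0.3 at age 100, truncated to [0, 1].

Per-CpG start/end levels are drawn uniformly (lo ~ U(0.10, 0.35),
hi ~ U(0.65, 0.90)) so that curves span the beta range while the logarithmic
and linear families stay deliberately adjacent — their confusion is a known
property of this benchmark design.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import BetaMatrix, SampleTable, ValidationError

__all__ = ["ARCHETYPES", "ArchetypeSpec", "SimulatedDataset", "archetype_mean", "simulate_dataset"]

_MU_LO, _MU_HI = 0.01, 0.99
_SIG_TAU = 5.0  # logistic time scale, years
_BUMP_CENTER, _BUMP_SD, _BUMP_AMP, _BUMP_BASE = 60.0, 20.0, 0.25, 0.35


@dataclass(frozen=True)
class ArchetypeSpec:
    """One trajectory archetype: name plus its deterministic mean function.

    ``mean_fn(age, lo, hi)`` maps ages to expectations given the per-CpG
    low/high methylation levels (ignored where not applicable).
    """

    name: str
    mean_fn: Callable[[np.ndarray, float, float], np.ndarray]
    uses_levels: bool = True
    beta_noise: bool = True


def _lin_inc(a, lo, hi):
    return lo + (hi - lo) * (a - 1.0) / 99.0


def _lin_dec(a, lo, hi):
    return hi - (hi - lo) * (a - 1.0) / 99.0


def _quad_inc(a, lo, hi):
    # vertex (zero slope) at age 1: slow start, accelerating gain
    return lo + (hi - lo) * ((a - 1.0) / 99.0) ** 2


def _quad_dec(a, lo, hi):
    # vertex at age 100: accelerating early loss that levels off late
    return lo + (hi - lo) * ((100.0 - a) / 99.0) ** 2


def _log_inc(a, lo, hi):
    return lo + (hi - lo) * np.log(a) / np.log(100.0)


def _log_dec(a, lo, hi):
    return hi - (hi - lo) * np.log(a) / np.log(100.0)


def _sig(a, lo, hi, x0, direction):
    s = 1.0 / (1.0 + np.exp(-(a - x0) / _SIG_TAU))
    return lo + (hi - lo) * s if direction > 0 else hi - (hi - lo) * s


def _nonmono(a, lo, hi):
    return _BUMP_BASE + _BUMP_AMP * np.exp(-0.5 * ((a - _BUMP_CENTER) / _BUMP_SD) ** 2)


def _flat(level):
    def fn(a, lo, hi):
        return np.full_like(np.asarray(a, dtype=float), level)

    return fn


ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec("NC", lambda a, lo, hi: np.full_like(np.asarray(a, float), lo),
                  uses_levels=False),
    ArchetypeSpec("LIN_INC", _lin_inc),
    ArchetypeSpec("LIN_DEC", _lin_dec),
    ArchetypeSpec("QUAD_INC", _quad_inc),
    ArchetypeSpec("QUAD_DEC", _quad_dec),
    ArchetypeSpec("LOG_INC", _log_inc),
    ArchetypeSpec("LOG_DEC", _log_dec),
    ArchetypeSpec("SIG_INC_25", lambda a, lo, hi: _sig(a, lo, hi, 25.0, +1)),
    ArchetypeSpec("SIG_INC_40", lambda a, lo, hi: _sig(a, lo, hi, 40.0, +1)),
    ArchetypeSpec("SIG_INC_80", lambda a, lo, hi: _sig(a, lo, hi, 80.0, +1)),
    ArchetypeSpec("SIG_DEC_25", lambda a, lo, hi: _sig(a, lo, hi, 25.0, -1)),
    ArchetypeSpec("SIG_DEC_40", lambda a, lo, hi: _sig(a, lo, hi, 40.0, -1)),
    ArchetypeSpec("SIG_DEC_80", lambda a, lo, hi: _sig(a, lo, hi, 80.0, -1)),
    ArchetypeSpec("VI", _flat(0.5), uses_levels=False, beta_noise=False),
    ArchetypeSpec("NONMONO", _nonmono, uses_levels=False),
)

_BY_NAME = {spec.name: spec for spec in ARCHETYPES}

# archetypes whose correct coarse classifier label is known a priori
COARSE_TRUTH: dict[str, str] = {
    "NC": "NC",
    "LIN_INC": "LI",
    "LIN_DEC": "LD",
    "QUAD_INC": "NL",
    "QUAD_DEC": "NL",
    "LOG_INC": "NL",
    "LOG_DEC": "NL",
    "SIG_INC_25": "NL",
    "SIG_INC_40": "NL",
    "SIG_INC_80": "NL",
    "SIG_DEC_25": "NL",
    "SIG_DEC_40": "NL",
    "SIG_DEC_80": "NL",
    "VI": "VI",
    "NONMONO": "NL",
}


def archetype_mean(spec: ArchetypeSpec | str, age, lo: float = 0.2, hi: float = 0.8):
    """Deterministic mean curve mu(age) of an archetype, clamped to (0.01, 0.99)."""
    if isinstance(spec, str):
        spec = _BY_NAME[spec]
    age = np.asarray(age, dtype=float)
    mu = spec.mean_fn(age, lo, hi)
    if np.any((mu < _MU_LO) | (mu > _MU_HI)):
        import warnings

        warnings.warn(f"{spec.name}: mean pushed outside ({_MU_LO}, {_MU_HI}); clamped")
    return np.clip(mu, _MU_LO, _MU_HI)


def _vi_sigma(age: np.ndarray) -> np.ndarray:
    """SD of the VI archetype: 0.01 below age 25, then linear to 0.3 at age 100."""
    age = np.asarray(age, dtype=float)
    return np.where(age < 25.0, 0.01, 0.01 + (0.3 - 0.01) * (age - 25.0) / 75.0)


@dataclass
class SimulatedDataset:
    beta: BetaMatrix
    ages: np.ndarray
    truth_labels: pd.Series  # archetype per CpG, indexed by cpg_id
    seed: int

    @property
    def sample_table(self) -> SampleTable:
        return SampleTable(
            pd.DataFrame({"sample_id": self.beta.sample_ids, "age": self.ages})
        )

    def coarse_truth(self) -> pd.Series:
        return self.truth_labels.map(COARSE_TRUTH)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.beta.frame.to_csv(outdir / "beta.csv", index_label="cpg_id")
        self.sample_table.frame.to_csv(outdir / "samples.csv", index_label="sample_id")
        self.truth_labels.rename("archetype").to_csv(outdir / "truth.csv", index_label="cpg_id")


def simulate_dataset(
    n_individuals: int = 300,
    n_per_class: int = 200,
    age_range: tuple[int, int] = (1, 100),
    phi: float = 100.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate the benchmark design: 15 archetypes x ``n_per_class`` CpGs.

    Ages are i.i.d. uniform integers over ``age_range``. Reproducible from
    ``seed``; identical seeds give identical matrices.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    if phi <= 0:
        raise ValidationError(f"beta precision phi must be > 0, got {phi}")
    rng = np.random.default_rng(seed)
    lo_age, hi_age = age_range
    ages = rng.integers(lo_age, hi_age + 1, size=n_individuals).astype(float)

    rows, ids, labels = [], [], []
    for spec in ARCHETYPES:
        for j in range(n_per_class):
            if spec.name == "NC":
                lo = hi = rng.uniform(0.2, 0.8)  # flat baseline level
            else:
                lo = rng.uniform(0.10, 0.35)
                hi = rng.uniform(0.65, 0.90)
            mu = archetype_mean(spec, ages, lo, hi)
            if spec.beta_noise:
                values = rng.beta(mu * phi, (1.0 - mu) * phi)
            else:
                sd = _vi_sigma(ages)
                a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
                values = truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
            rows.append(values)
            ids.append(f"cpg_{spec.name}_{j:04d}")
            labels.append(spec.name)

    frame = pd.DataFrame(
        np.vstack(rows),
        index=pd.Index(ids, name="cpg_id"),
        columns=[f"s{i:04d}" for i in range(n_individuals)],
    )
    beta = BetaMatrix(frame.clip(0.0, 1.0))
    truth = pd.Series(labels, index=frame.index, name="archetype")
    return SimulatedDataset(beta=beta, ages=ages, truth_labels=truth, seed=seed)
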