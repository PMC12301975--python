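"""Bliss-independence genetic-interaction inference on lesion incidence.

The Bliss null for two binary perturbations states that the combined
incidence equals ``E = p_A + p_B - p_A * p_B``; the synergy score at a fixed
horizon is the observed double-knockout incidence minus ``E``.  Uncertainty is
quantified by a within-genotype percentile bootstrap and a parametric-
resampling test of the independence null (see :func:`synergy_permutation_p`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import stream_rng
from .survival import incidence_at, km_estimate

__all__ = [
    "SynergyResult",
    "bliss_expected",
    "synergy_score",
    "synergy_ci",
    "synergy_permutation_p",
    "synergy_at",
    "synergy_timecourse",
    "fisher_exact",
]

GENOTYPE_A = "SIRT2KO"
GENOTYPE_B = "SOD1KO"
GENOTYPE_AB = "DKO"


@dataclass
class SynergyResult:
    """Synergy inference at one horizon; scores rounded only for display."""

    horizon: float
    p_ab: float
    p_a: float
    p_b: float
    expected: float
    score: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_perm: float | None = None
    n_boot: int = 0
    n_perm: int = 0
    seed: int | None = None
    method: str = "crude"

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "p_ab": self.p_ab,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "expected": self.expected,
            "score": self.score,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_perm": self.p_perm,
            "n_boot": self.n_boot,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "method": self.method,
        }


def _check_prob(name: str, p: float) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
    return p


def bliss_expected(p_a: float, p_b: float) -> float:
    """Bliss-independent expected combined incidence ``p_A + p_B - p_A p_B``."""
    p_a = _check_prob("p_a", p_a)
    p_b = _check_prob("p_b", p_b)
    return p_a + p_b - p_a * p_b


def synergy_score(p_ab: float, p_a: float, p_b: float) -> float:
    """Observed combined incidence minus the Bliss expectation (>0 = synergy)."""
    p_ab = _check_prob("p_ab", p_ab)
    return p_ab - bliss_expected(p_a, p_b)


def _crude_arm(cohort: pd.DataFrame, genotype: str, t: float) -> tuple[int, int]:
    """(lesioned-by-t, eligible) counts feeding the crude incidence."""
    sub = cohort[cohort["genotype"] == genotype]
    if len(sub) < 2:
        raise ValueError(f"need >= 2 subjects of genotype {genotype!r}")
    times = sub["lesion_time"].to_numpy(dtype=float)
    events = sub["lesion_event"].to_numpy(dtype=int)
    lesioned = (events == 1) & (times <= t)
    eligible = lesioned | (times >= t)
    n = int(eligible.sum())
    if n == 0:
        raise ValueError(f"no eligible {genotype} subjects at day {t}")
    return int(lesioned.sum()), n


def _km_incidence_boot(
    sub: pd.DataFrame, t: float, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """KM-complement incidences from subject-index bootstrap of one arm."""
    times = sub["lesion_time"].to_numpy(dtype=float)
    events = sub["lesion_event"].to_numpy(dtype=int)
    n = times.size
    out = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        if events[idx].sum() == 0:
            out[i] = 0.0
        else:
            out[i] = 1.0 - km_estimate(times[idx], events[idx]).survival_at(t)
    return out


def _boot_incidences(
    cohort: pd.DataFrame,
    t: float,
    n_boot: int,
    rng: np.random.Generator,
    method: str,
) -> dict[str, np.ndarray]:
    """Bootstrap incidence draws per genotype arm.

    For the crude estimator, resampling the eligible subjects with
    replacement is exactly a binomial draw on the observed proportion, which
    is what is done (vectorised).  For the KM complement the subject indices
    of the whole arm are resampled.
    """
    out = {}
    for g in (GENOTYPE_A, GENOTYPE_B, GENOTYPE_AB):
        if method == "crude":
            k, n = _crude_arm(cohort, g, t)
            out[g] = rng.binomial(n, k / n, n_boot) / n
        else:
            sub = cohort[cohort["genotype"] == g]
            if len(sub) < 2:
                raise ValueError(f"need >= 2 subjects of genotype {g!r}")
            out[g] = _km_incidence_boot(sub, t, n_boot, rng)
    return out


def synergy_ci(
    cohort: pd.DataFrame,
    t: float,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "crude",
) -> tuple[float, float]:
    """95 % percentile-bootstrap CI of the synergy score at horizon ``t``.

    Resamples with replacement within each genotype arm and recomputes the
    score per replicate; deterministic under ``seed``.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable")
    rng = stream_rng(seed, "synergy-boot")
    draws = _boot_incidences(cohort, t, int(n_boot), rng, method)
    scores = draws[GENOTYPE_AB] - (
        draws[GENOTYPE_A] + draws[GENOTYPE_B] - draws[GENOTYPE_A] * draws[GENOTYPE_B]
    )
    lo, hi = np.percentile(scores, [2.5, 97.5])
    return float(lo), float(hi)


def synergy_permutation_p(
    cohort: pd.DataFrame,
    t: float,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "crude",
) -> float:
    """One-sided resampling test of the Bliss-independence null.

    Each null replicate resamples the two single-knockout arms to get an
    expected rate ``E*``, simulates the DKO arm as independent Bernoulli
    trials at rate ``E*``, and scores it against the observed expected
    incidence.  The add-one estimator ``(1 + #{S_null >= S_obs}) /
    (n_perm + 1)`` is one-sided toward synergy.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = stream_rng(seed, "synergy-perm")
    obs = {
        g: incidence_at(cohort, g, t, method=method).incidence
        for g in (GENOTYPE_A, GENOTYPE_B, GENOTYPE_AB)
    }
    e_obs = bliss_expected(obs[GENOTYPE_A], obs[GENOTYPE_B])
    s_obs = obs[GENOTYPE_AB] - e_obs

    n_perm = int(n_perm)
    if method == "crude":
        k_a, n_a = _crude_arm(cohort, GENOTYPE_A, t)
        k_b, n_b = _crude_arm(cohort, GENOTYPE_B, t)
        _, n_ab = _crude_arm(cohort, GENOTYPE_AB, t)
        p_a_null = rng.binomial(n_a, k_a / n_a, n_perm) / n_a
        p_b_null = rng.binomial(n_b, k_b / n_b, n_perm) / n_b
    else:
        rng_a = stream_rng(seed, "synergy-perm-a")
        rng_b = stream_rng(seed, "synergy-perm-b")
        p_a_null = _km_incidence_boot(
            cohort[cohort["genotype"] == GENOTYPE_A], t, n_perm, rng_a
        )
        p_b_null = _km_incidence_boot(
            cohort[cohort["genotype"] == GENOTYPE_B], t, n_perm, rng_b
        )
        n_ab = int((cohort["genotype"] == GENOTYPE_AB).sum())
    e_null = p_a_null + p_b_null - p_a_null * p_b_null
    p_ab_null = rng.binomial(n_ab, e_null, n_perm) / n_ab
    s_null = p_ab_null - e_obs
    return float((1 + int((s_null >= s_obs).sum())) / (n_perm + 1))


def synergy_at(
    cohort: pd.DataFrame,
    t: float,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "crude",
) -> SynergyResult:
    """Full synergy inference (point score, bootstrap CI, permutation p) at ``t``."""
    p_a = incidence_at(cohort, GENOTYPE_A, t, method=method).incidence
    p_b = incidence_at(cohort, GENOTYPE_B, t, method=method).incidence
    p_ab = incidence_at(cohort, GENOTYPE_AB, t, method=method).incidence
    expected = bliss_expected(p_a, p_b)
    ci_low, ci_high = synergy_ci(cohort, t, n_boot=n_boot, seed=seed, method=method)
    p_perm = synergy_permutation_p(cohort, t, n_perm=n_perm, seed=seed, method=method)
    return SynergyResult(
        horizon=t,
        p_ab=p_ab,
        p_a=p_a,
        p_b=p_b,
        expected=expected,
        score=p_ab - expected,
        ci_low=ci_low,
        ci_high=ci_high,
        p_perm=p_perm,
        n_boot=int(n_boot),
        n_perm=int(n_perm),
        seed=seed,
        method=method,
    )


def synergy_timecourse(
    cohort: pd.DataFrame,
    horizons,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "crude",
) -> list[SynergyResult]:
    """Synergy inference at each horizon of an ascending sequence."""
    horizons = list(horizons)
    if horizons != sorted(horizons):
        raise ValueError("horizons must be sorted ascending")
    return [
        synergy_at(cohort, t, n_boot=n_boot, n_perm=n_perm, seed=seed, method=method)
        for t in horizons
    ]


def fisher_exact(table) -> tuple[float, float]:
    """Two-tailed Fisher's exact test on a 2x2 table.

    Returns the conditional maximum-likelihood odds ratio (0/inf on zero
    cells) and the probability-mass two-tailed p (sum of all tables, at the
    observed margins, whose point probability does not exceed the observed
    one).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("cells must be nonnegative integers")
        arr = arr.astype(int)
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    oddsratio = float(stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    return oddsratio, float(p)
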