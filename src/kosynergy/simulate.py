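"""Synthetic cohorts, differential-expression tables and count matrices.

Everything downstream of the animal study and the RNA-seq pipeline is driven
from these generators, so every analysis stage is testable against planted
truth without external data.  All draws come from named streams of one global
seed (see :func:`kosynergy.config.stream_rng`): identical configuration and
seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import GENOTYPES, SimulationConfig

COHORT_COLUMNS = (
    "subject_id",
    "genotype",
    "lesion_time",
    "lesion_event",
    "followup_time",
    "death_event",
)

DEG_COLUMNS = ("gene_id", "log2fc", "pvalue", "padj", "mean_count", "transcript_length")

# Log-normal shape of per-gene baseline abundance and transcript length.
_MEANCOUNT_MEANLOG, _MEANCOUNT_SDLOG = 5.5, 1.2
_LENGTH_MEANLOG, _LENGTH_SDLOG = np.log(2000.0), 0.9
_BASEMEAN_MEANLOG, _BASEMEAN_SDLOG = 5.0, 1.0


def _exponential_days(rng: np.random.Generator, hazard: float, n: int) -> np.ndarray:
    """Integer event days (>= 1) from a constant hazard; inf when hazard is 0."""
    if hazard <= 0:
        return np.full(n, np.inf)
    return np.ceil(rng.exponential(1.0 / hazard, n))


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate one four-genotype cohort with right censoring.

    Lesion onset is exponential with the per-genotype hazard (the DKO hazard
    is ``theta`` times the Bliss-independent sum of the single-knockout
    hazards).  Subjects leave observation at an exponential attrition time
    (``death_event = 1``) or administratively at ``followup_days``
    (``death_event = 0``), whichever is first; lesions are observed only up to
    that time.  Times are whole days >= 1.
    """
    rng = config.stream("cohort")
    frames = []
    for genotype in GENOTYPES:
        n = config.n_per_genotype
        lesion_latent = _exponential_days(rng, config.hazard_for(genotype), n)
        attrition = _exponential_days(rng, config.censor_hazard, n)
        followup_time = np.minimum(attrition, config.followup_days)
        death_event = (attrition <= config.followup_days).astype(int)
        lesion_event = (lesion_latent <= followup_time).astype(int)
        lesion_time = np.where(lesion_event == 1, lesion_latent, followup_time)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{genotype}_{i:03d}" for i in range(n)],
                    "genotype": genotype,
                    "lesion_time": lesion_time.astype(int),
                    "lesion_event": lesion_event,
                    "followup_time": followup_time.astype(int),
                    "death_event": death_event,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class DegTruth:
    """Hidden truth behind a simulated DE table.

    ``labels`` maps gene_id -> {"up", "down", "null"}; ``gene_sets`` holds the
    planted memberships usable as enrichment ground truth.
    """

    labels: pd.Series
    gene_sets: dict[str, frozenset]


def simulate_deg_table(
    config: SimulationConfig, noise_stream: str = "deg"
) -> tuple[pd.DataFrame, DegTruth]:
    """Simulate a differential-expression result table with planted structure.

    A fraction ``frac_up`` of genes gets true effect ``+effect_log2fc`` and
    ``frac_down`` gets ``-effect_log2fc``; the rest are null.  The observed
    log2 fold change adds Gaussian noise with standard deviation ``noise_sd``
    and the p-value is the two-sided Gaussian test of that estimate, so null
    genes have exactly uniform p-values.  When ``length_shift`` is nonzero the
    planted up-regulated transcripts are shortened by that amount on the log
    scale, emulating the aging-associated length imbalance.

    The planted truth is drawn from its own stream of the seed, so tables
    generated under different ``noise_stream`` names (e.g. one per tissue)
    share one underlying truth while their noise is independent — the
    substrate for cross-tissue signature analyses.
    """
    rng_truth = config.stream("deg-truth")
    rng = config.stream(noise_stream)
    n = config.n_genes
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    if n_up + n_down > n:
        raise ValueError("frac_up + frac_down > 1")

    gene_ids = np.array([f"gene{i:05d}" for i in range(n)])
    labels = np.array(["null"] * n, dtype=object)
    planted = rng_truth.choice(n, size=n_up + n_down, replace=False)
    up_idx, down_idx = planted[:n_up], planted[n_up:]
    labels[up_idx] = "up"
    labels[down_idx] = "down"

    true_lfc = np.zeros(n)
    true_lfc[up_idx] = config.effect_log2fc
    true_lfc[down_idx] = -config.effect_log2fc

    log2fc = true_lfc + rng.normal(0.0, config.noise_sd, n)
    z = log2fc / config.noise_sd
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    from .transcriptome import bh_adjust  # local import avoids a cycle at import time

    padj = bh_adjust(pvalue)
    mean_count = rng.lognormal(_MEANCOUNT_MEANLOG, _MEANCOUNT_SDLOG, n)
    meanlog = np.full(n, _LENGTH_MEANLOG)
    meanlog[up_idx] -= config.length_shift
    transcript_length = np.maximum(1, np.round(rng.lognormal(meanlog, _LENGTH_SDLOG))).astype(int)

    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "mean_count": mean_count,
            "transcript_length": transcript_length,
        }
    )
    n_decoy = min(100, n - n_up - n_down)
    null_ids = gene_ids[labels == "null"]
    decoy = (
        rng_truth.choice(null_ids, size=n_decoy, replace=False)
        if n_decoy
        else np.array([])
    )
    truth = DegTruth(
        labels=pd.Series(labels, index=gene_ids, name="label"),
        gene_sets={
            "planted_up": frozenset(gene_ids[up_idx]),
            "planted_down": frozenset(gene_ids[down_idx]),
            "decoy_null": frozenset(decoy),
        },
    )
    return table, truth


def simulate_counts(
    config: SimulationConfig,
    base_means: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series, DegTruth]:
    """Simulate an overdispersed gene-by-sample count matrix with two groups.

    Counts follow a gamma-Poisson (negative-binomial-type) model with
    variance ``mu + dispersion * mu**2``.  Planted genes have their treated-
    group mean scaled by ``2 ** (+/- effect_log2fc)``.  Returns the count
    matrix, the per-sample group labels ("control"/"treated") and the hidden
    truth.
    """
    if config.n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    rng = config.stream("counts")
    n = config.n_genes
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))

    gene_ids = np.array([f"gene{i:05d}" for i in range(n)])
    labels = np.array(["null"] * n, dtype=object)
    planted = rng.choice(n, size=n_up + n_down, replace=False)
    up_idx, down_idx = planted[:n_up], planted[n_up:]
    labels[up_idx] = "up"
    labels[down_idx] = "down"

    if base_means is None:
        base_means = rng.lognormal(_BASEMEAN_MEANLOG, _BASEMEAN_SDLOG, n)
    else:
        base_means = np.asarray(base_means, dtype=float)
        if base_means.shape != (n,):
            raise ValueError(f"base_means must have shape ({n},)")
    fold = np.ones(n)
    fold[up_idx] = 2.0**config.effect_log2fc
    fold[down_idx] = 2.0**-config.effect_log2fc

    m = config.n_samples_per_group
    sample_ids = [f"control_{i}" for i in range(m)] + [f"treated_{i}" for i in range(m)]
    groups = pd.Series(["control"] * m + ["treated"] * m, index=sample_ids, name="group")

    mu = np.column_stack([np.repeat(base_means[:, None], m, axis=1),
                          np.repeat((base_means * fold)[:, None], m, axis=1)])
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    truth = DegTruth(
        labels=pd.Series(labels, index=gene_ids, name="label"),
        gene_sets={
            "planted_up": frozenset(gene_ids[up_idx]),
            "planted_down": frozenset(gene_ids[down_idx]),
        },
    )
    return counts_df, groups, truth
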