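"""Downstream transcriptome statistics.

Expression filtering, BH adjustment, the signed ranking metric, pre-ranked
gene-set enrichment (weighted Kolmogorov–Smirnov running sum with gene-label
permutation), transcript-length imbalance, cross-tissue core signatures,
paired fold-change comparison, marker-based immune scoring, and a simple
two-group DE test used by the synthetic pipelines.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_expressed",
    "bh_adjust",
    "call_degs",
    "rank_metric",
    "make_ranked_list",
    "GseaResult",
    "gsea_preranked",
    "LengthImbalanceResult",
    "length_imbalance",
    "wilcoxon_ranksum",
    "SignatureResult",
    "core_signature",
    "FoldChangeComparison",
    "foldchange_comparison",
    "immune_score",
    "simple_de_test",
]

#: Genes must exceed this count in at least MIN_SAMPLES samples to be kept.
COUNT_THRESHOLD = 10
MIN_SAMPLES = 3

#: Combined sample size at or below which rank tests are computed exactly.
EXACT_RANK_LIMIT = 12

_PADJ_FLOOR = 1e-300


def filter_expressed(counts: pd.DataFrame) -> list[str]:
    """Genes with counts strictly greater than 10 in at least 3 samples."""
    arr = counts.to_numpy()
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if counts.shape[1] < MIN_SAMPLES:
        warnings.warn(
            f"fewer than {MIN_SAMPLES} samples: no gene can pass the expression filter"
        )
    keep = (arr > COUNT_THRESHOLD).sum(axis=1) >= MIN_SAMPLES
    return list(counts.index[keep])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(table: pd.DataFrame) -> tuple[set[str], set[str]]:
    """DEG calls: up = {log2fc > 1 and padj < 0.05}, down mirrored (strict)."""
    up = set(table.loc[(table["log2fc"] > 1) & (table["padj"] < 0.05), "gene_id"])
    down = set(table.loc[(table["log2fc"] < -1) & (table["padj"] < 0.05), "gene_id"])
    return up, down


def rank_metric(padj, log2fc):
    """Signed ranking score ``-log10(padj) * sign(fold change)``.

    Accepts scalars or arrays.  ``padj == 0`` is clamped to the smallest
    representable positive value (with a warning) so scores stay finite;
    ``log2fc == 0`` has no defined sign and scores 0 (with a warning).
    """
    padj_arr = np.atleast_1d(np.asarray(padj, dtype=float))
    lfc_arr = np.atleast_1d(np.asarray(log2fc, dtype=float))
    if np.any((padj_arr < 0) | (padj_arr > 1)):
        raise ValueError("padj must lie in [0, 1]")
    if np.any(padj_arr == 0):
        warnings.warn(f"padj of 0 clamped to {_PADJ_FLOOR:g}")
        padj_arr = np.where(padj_arr == 0, _PADJ_FLOOR, padj_arr)
    if np.any(lfc_arr == 0):
        warnings.warn("log2fc of 0 has no sign; ranking score set to 0")
    score = -np.log10(padj_arr) * np.sign(lfc_arr)
    return float(score[0]) if np.isscalar(padj) or np.ndim(padj) == 0 else score


def make_ranked_list(table: pd.DataFrame) -> pd.Series:
    """Ranked gene list (score descending) from a DE table.

    Ties in score are broken by gene id, lexicographically ascending, so the
    ordering is deterministic across platforms.
    """
    if table["gene_id"].duplicated().any():
        raise ValueError("gene ids must be unique")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = rank_metric(table["padj"].to_numpy(), table["log2fc"].to_numpy())
    ranked = pd.DataFrame({"gene_id": table["gene_id"].to_numpy(), "score": scores})
    ranked = ranked.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return pd.Series(ranked["score"].to_numpy(), index=ranked["gene_id"].to_numpy())


# --------------------------------------------------------------------------
# Pre-ranked GSEA
# --------------------------------------------------------------------------

@dataclass
class GseaResult:
    name: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr: float
    leading_edge: list[str]


def _running_sum_extreme(
    abs_scores: np.ndarray, positions: np.ndarray, weight: float
) -> tuple[float, int]:
    """Enrichment score of a hit set given by sorted 0-based ``positions``.

    Hits increment the running sum proportionally to ``|score|**weight``
    (normalised to sum 1); misses decrement uniformly by ``1/(N - k)``.  The
    score is the deviation of largest magnitude; the peak position index into
    ``positions`` is returned for leading-edge extraction (negative index
    convention: ``(es, i)`` with ``es >= 0`` peaks just after hit ``i``,
    ``es < 0`` dips just before hit ``i``).
    """
    n = abs_scores.size
    k = positions.size
    if k == 0 or k >= n:
        raise ValueError("hit set must be a nonempty proper subset of the list")
    w = abs_scores[positions] ** weight if weight != 0 else np.ones(k)
    total = w.sum()
    if total == 0:  # all hit scores are exactly zero: fall back to unweighted
        w = np.ones(k)
        total = float(k)
    cum = np.cumsum(w) / total
    miss = 1.0 / (n - k)
    offsets = positions - np.arange(k)  # misses strictly before each hit
    after = cum - offsets * miss  # running sum just after each hit
    before = after - w / total  # running sum just before each hit
    # magnitude ties (up to rounding; running-sum values are bounded by 1 so
    # an absolute tolerance is adequate) resolve to the deviation reached
    # first along the list: the positive peak sits at its hit, the negative
    # dip just before its hit
    tol = 1e-12
    i_max = int(np.nonzero(after >= after.max() - tol)[0][0])
    i_min = int(np.nonzero(before <= before.min() + tol)[0][0])
    pos_dev = max(float(after[i_max]), 0.0)
    neg_dev = min(float(before[i_min]), 0.0)
    if pos_dev > -neg_dev + tol:
        return pos_dev, i_max
    if -neg_dev > pos_dev + tol:
        return neg_dev, i_min
    if pos_dev <= tol:
        return 0.0, i_max
    if positions[i_min] - 1 < positions[i_max]:
        return neg_dev, i_min
    return pos_dev, i_max


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: dict,
    weight: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 500,
    seed: int = 0,
) -> list[GseaResult]:
    """Pre-ranked GSEA over a collection of gene sets.

    ``ranked`` maps gene id -> score, sorted descending (see
    :func:`make_ranked_list`).  The null distribution comes from ``n_perm``
    gene-label permutations (random same-size hit sets); NES divides ES by the
    mean magnitude of same-sign null scores, the permutation p is the add-one
    one-sided tail among same-sign nulls, and FDR is BH across the reported
    sets.  Sets whose intersection with the list falls outside
    ``[min_size, max_size]`` are skipped with a warning.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; permutation p will be coarse")
    scores = ranked.to_numpy(dtype=float)
    if np.any(np.diff(scores) > 0):
        raise ValueError("ranked scores must be nonincreasing")
    genes = np.asarray(ranked.index)
    if len(set(genes)) != genes.size:
        raise ValueError("ranked list contains duplicate genes")
    abs_scores = np.abs(scores)
    index_of = {g: i for i, g in enumerate(genes)}
    n = genes.size
    rng = np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(0x65A5,))
    )

    results: list[GseaResult] = []
    for name, members in gene_sets.items():
        positions = np.sort([index_of[g] for g in set(members) if g in index_of])
        k = positions.size
        if k == 0:
            raise ValueError(f"gene set {name!r} has empty intersection with the list")
        if not (min_size <= k <= max_size):
            warnings.warn(
                f"gene set {name!r} skipped: intersection size {k} outside "
                f"[{min_size}, {max_size}]"
            )
            continue
        es, peak = _running_sum_extreme(abs_scores, positions, weight)
        null = np.empty(int(n_perm))
        for i in range(int(n_perm)):
            perm_pos = np.sort(rng.choice(n, size=k, replace=False))
            null[i], _ = _running_sum_extreme(abs_scores, perm_pos, weight)
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            nes = float("nan")
            p_perm = 1.0 / (int(n_perm) + 1)
        else:
            denom = np.abs(same_sign).mean()
            nes = float(es / denom) if denom > 0 else float("nan")
            p_perm = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (
                same_sign.size + 1
            )
        if es > 0:
            leading = [genes[p] for p in positions[: peak + 1]]
        elif es < 0:
            leading = [genes[p] for p in positions[peak:]]
        else:
            leading = []
        results.append(
            GseaResult(
                name=name, size=k, es=es, nes=nes, p_perm=float(p_perm),
                fdr=float("nan"), leading_edge=list(leading),
            )
        )
    if results:
        fdrs = bh_adjust([r.p_perm for r in results])
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return results


# --------------------------------------------------------------------------
# Rank tests
# --------------------------------------------------------------------------

def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Uses average ranks for ties; feasible for combined n <= 12
    (C(12,6) = 924 assignments).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    m = x.size
    obs = ranks[:m].sum()
    center = m * (pooled.size + 1) / 2.0
    obs_dev = abs(obs - center)
    hits = total = 0
    for combo in itertools.combinations(range(pooled.size), m):
        total += 1
        if abs(ranks[list(combo)].sum() - center) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum test (two-sided), exact for combined n <= 12.

    Returns ``(U, p)`` where U is the Mann–Whitney statistic of ``x``.  Above
    the exact limit the normal approximation with continuity correction is
    used; ties get average ranks in both regimes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_stat = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    if x.size + y.size <= EXACT_RANK_LIMIT:
        return u_stat, _exact_ranksum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_stat, float(res.pvalue)


@dataclass
class LengthImbalanceResult:
    median_up: float
    median_down: float
    statistic: float
    pvalue: float
    direction: str  # "up-shorter" | "down-shorter" | "none"
    n_up: int
    n_down: int


def length_imbalance(table: pd.DataFrame) -> LengthImbalanceResult:
    """Transcript-length comparison of up- vs down-regulated DEGs.

    Aging-associated transcriptomes show systematically shorter up-regulated
    transcripts; this compares the transcript lengths of the two DEG sets by
    a two-sided rank-sum test and reports the medians and direction.
    """
    up, down = call_degs(table)
    lengths = table.set_index("gene_id")["transcript_length"]
    up_len = lengths.loc[sorted(up)].dropna().to_numpy(dtype=float)
    down_len = lengths.loc[sorted(down)].dropna().to_numpy(dtype=float)
    if up_len.size == 0 or down_len.size == 0:
        raise ValueError(
            "length imbalance undefined: need at least one up- and one down-regulated DEG"
        )
    stat, p = wilcoxon_ranksum(up_len, down_len)
    med_up = float(np.median(up_len))
    med_down = float(np.median(down_len))
    if med_up < med_down:
        direction = "up-shorter"
    elif med_up > med_down:
        direction = "down-shorter"
    else:
        direction = "none"
    return LengthImbalanceResult(
        median_up=med_up, median_down=med_down, statistic=stat, pvalue=p,
        direction=direction, n_up=up_len.size, n_down=down_len.size,
    )


# --------------------------------------------------------------------------
# Signatures and comparisons
# --------------------------------------------------------------------------

@dataclass
class SignatureResult:
    per_tissue: dict
    intersection: list[str]
    pairwise_overlap: dict


def core_signature(per_tissue_up: dict) -> SignatureResult:
    """Genes shared by every tissue's regulated set, plus pairwise overlaps."""
    if not per_tissue_up:
        raise ValueError("empty tissue mapping")
    if len(per_tissue_up) < 2:
        raise ValueError("need at least 2 tissues")
    sets = {t: set(s) for t, s in per_tissue_up.items()}
    inter = set.intersection(*sets.values())
    pairs = {
        (a, b): len(sets[a] & sets[b])
        for a, b in itertools.combinations(sorted(sets), 2)
    }
    return SignatureResult(
        per_tissue=sets, intersection=sorted(inter), pairwise_overlap=pairs
    )


@dataclass
class FoldChangeComparison:
    median_difference: float
    pvalue: float
    pairs: pd.DataFrame  # gene_id, fc_double, fc_single, difference


def foldchange_comparison(
    common_genes, fc_double: dict, fc_single: dict
) -> FoldChangeComparison:
    """Paired comparison of per-gene fold changes (double minus single KO).

    Wilcoxon signed-rank, two-sided, exact for n <= 12 tie-free cases (scipy's
    automatic switch); identical mappings give p = 1 by convention.
    """
    genes = sorted(common_genes)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in fc_double or g not in fc_single]
    if missing:
        raise ValueError(f"genes missing from a fold-change mapping: {missing[:5]}")
    d = np.array([fc_double[g] for g in genes], dtype=float)
    s = np.array([fc_single[g] for g in genes], dtype=float)
    diff = d - s
    pairs = pd.DataFrame(
        {"gene_id": genes, "fc_double": d, "fc_single": s, "difference": diff}
    )
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        p = 1.0
    else:
        p = float(stats.wilcoxon(d, s, alternative="two-sided").pvalue)
    return FoldChangeComparison(
        median_difference=float(np.median(diff)), pvalue=p, pairs=pairs
    )


def immune_score(expr: pd.DataFrame, marker_sets: dict) -> pd.DataFrame:
    """Marker-mean immune-population scores, z-scored across samples.

    A deliberately simple marker-gene analogue of murine immune-deconvolution
    scoring: the score of a population in a sample is the mean log-scale
    expression of its marker genes, standardised across samples (population
    standard deviation).  Scores are comparative across samples only, not
    absolute cell proportions.  Markers absent from the matrix are dropped
    with a warning; populations with fewer than 2 remaining markers are
    skipped.
    """
    scores = {}
    for pop, markers in marker_sets.items():
        present = [g for g in sorted(set(markers)) if g in expr.index]
        missing = sorted(set(markers) - set(present))
        if missing:
            warnings.warn(f"population {pop!r}: {len(missing)} marker(s) not in matrix")
        if len(present) < 2:
            warnings.warn(f"population {pop!r} skipped: fewer than 2 markers present")
            continue
        means = expr.loc[present].mean(axis=0)
        sd = float(means.std(ddof=0))
        scores[pop] = (means - means.mean()) / sd if sd > 0 else means * 0.0
    if not scores:
        raise ValueError("no population could be scored")
    return pd.DataFrame(scores)


def simple_de_test(
    counts: pd.DataFrame,
    groups,
    transcript_lengths: dict | None = None,
) -> pd.DataFrame:
    """Two-group differential-expression test on a count matrix.

    Library-size normalisation (counts scaled so all samples share the mean
    library size), log2 with pseudo-count 0.5, per-gene Welch t-test, BH
    adjustment.  The log2 fold change is the difference of group means of the
    log values, second group level (sorted order) minus first.  This is a
    plain two-group screen for synthetic pipelines, not a negative-binomial
    model.
    """
    groups = pd.Series(np.asarray(groups), index=counts.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    ref_cols = groups[groups == levels[0]].index
    alt_cols = groups[groups == levels[1]].index
    if len(ref_cols) < 2 or len(alt_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    libsize = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(libsize == 0):
        raise ValueError("a sample has zero total counts")
    norm = counts.to_numpy(dtype=float) * (libsize.mean() / libsize)
    log = np.log2(norm + 0.5)
    log_df = pd.DataFrame(log, index=counts.index, columns=counts.columns)
    a = log_df[ref_cols].to_numpy()
    b = log_df[alt_cols].to_numpy()
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    pvalue = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    table = pd.DataFrame(
        {
            "gene_id": counts.index.to_numpy(),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "mean_count": norm.mean(axis=1),
            "transcript_length": [
                (transcript_lengths or {}).get(g, np.nan) for g in counts.index
            ],
        }
    )
    return table.reset_index(drop=True)
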