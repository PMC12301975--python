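"""End-to-end pipeline: simulate (optionally), then run the requested stages.

Every artifact directory is stamped with the package version, a hash of the
configuration and the seed, and re-running with an identical configuration
reproduces byte-identical JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as kio
from .config import GENOTYPES, SimulationConfig
from .simulate import simulate_cohort, simulate_counts, simulate_deg_table
from .survival import km_estimate, logrank, median_survival
from .synergy import synergy_timecourse
from .transcriptome import (
    call_degs,
    core_signature,
    gsea_preranked,
    immune_score,
    length_imbalance,
    make_ranked_list,
)

log = logging.getLogger("kosynergy")


@dataclass
class PipelineConfig:
    """Paths, horizons, resampling sizes and method flags for one run.

    Input paths may be omitted when ``simulate`` is set, in which case the
    named inputs are generated into ``outdir/inputs`` first.
    """

    outdir: str
    seed: int
    horizons: list[int] = field(default_factory=lambda: [100, 200, 300, 400])
    n_boot: int = 1000
    n_perm: int = 1000
    incidence_method: str = "crude"
    gsea_weight: float = 1.0
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    cohort: str | None = None
    deg_tables: dict[str, str] = field(default_factory=dict)  # tissue -> path
    gmt: str | None = None
    counts: str | None = None
    marker_gmt: str | None = None
    simulate: SimulationConfig | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the analysis configuration (the output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a mapping stage name -> artifact path(s); any stage failure
    aborts with the stage name and cause.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = config.config_hash()  # hash of the *requested* configuration
    artifacts: dict[str, object] = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)

    def _require(path, label):
        if path is None:
            return None
        if not Path(path).exists():
            raise FileNotFoundError(f"{label} file not found: {path}")
        return path

    # ---- optional simulation of inputs -----------------------------------
    def do_simulate():
        sim = config.simulate
        assert sim is not None
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        cohort = simulate_cohort(sim)
        kio.write_cohort(cohort, inputs / "cohort.tsv")
        config.cohort = str(inputs / "cohort.tsv")
        gene_sets = None
        for tissue in ("liver", "skin", "spleen"):
            # shared planted truth, per-tissue noise
            table, truth = simulate_deg_table(sim, noise_stream=f"deg-{tissue}")
            kio.write_deg(table, inputs / f"deg_{tissue}.tsv")
            config.deg_tables[tissue] = str(inputs / f"deg_{tissue}.tsv")
            truth.labels.rename_axis("gene_id").reset_index().to_csv(
                inputs / f"truth_{tissue}.tsv", sep="\t", index=False
            )
            if gene_sets is None:
                gene_sets = {k: set(v) for k, v in truth.gene_sets.items()}
        kio.write_gmt(gene_sets, inputs / "planted_sets.gmt")
        config.gmt = str(inputs / "planted_sets.gmt")
        counts, groups, _ = simulate_counts(sim)
        kio.write_counts(counts, inputs / "counts.tsv")
        config.counts = str(inputs / "counts.tsv")

    if config.simulate is not None:
        stage("simulate", do_simulate)

    # ---- survival + synergy ---------------------------------------------
    def do_synergy():
        cohort = kio.read_cohort(_require(config.cohort, "cohort"))
        results = synergy_timecourse(
            cohort,
            config.horizons,
            n_boot=config.n_boot,
            n_perm=config.n_perm,
            seed=config.seed,
            method=config.incidence_method,
        )
        _dump_json([r.to_dict() for r in results], out / "synergy.json")
        pd.DataFrame([r.to_dict() for r in results]).to_csv(
            out / "synergy.tsv", sep="\t", index=False
        )
        artifacts["synergy"] = str(out / "synergy.json")

    def do_survival():
        cohort = kio.read_cohort(_require(config.cohort, "cohort"))
        summary = {}
        for g in GENOTYPES:
            sub = cohort[cohort["genotype"] == g]
            curve = km_estimate(sub["lesion_time"], sub["lesion_event"])
            summary[g] = {
                "n": int(len(sub)),
                "events": int(sub["lesion_event"].sum()),
                "median_lesion_free_days": median_survival(curve),
            }
        dko = cohort[cohort["genotype"] == "DKO"]
        comparisons = {}
        for g in ("WT", "SIRT2KO", "SOD1KO"):
            other = cohort[cohort["genotype"] == g]
            res = logrank(
                (dko["lesion_time"], dko["lesion_event"]),
                (other["lesion_time"], other["lesion_event"]),
            )
            comparisons[f"DKO_vs_{g}"] = {"chi2": res.chi2, "pvalue": res.pvalue}
        _dump_json(
            {"per_genotype": summary, "logrank": comparisons}, out / "survival.json"
        )
        artifacts["survival"] = str(out / "survival.json")

    if config.cohort is not None:
        stage("synergy", do_synergy)
        stage("survival", do_survival)

    # ---- transcriptome stages -------------------------------------------
    def do_gsea():
        gene_sets = kio.read_gmt(_require(config.gmt, "GMT"))
        rows = []
        for tissue, path in sorted(config.deg_tables.items()):
            table = kio.read_deg(_require(path, f"DEG table ({tissue})"))
            ranked = make_ranked_list(table)
            for r in gsea_preranked(
                ranked,
                gene_sets,
                weight=config.gsea_weight,
                n_perm=config.n_perm,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
                seed=config.seed,
            ):
                rows.append(
                    {
                        "tissue": tissue, "set": r.name, "size": r.size,
                        "es": r.es, "nes": r.nes, "p_perm": r.p_perm, "fdr": r.fdr,
                        "leading_edge_size": len(r.leading_edge),
                    }
                )
        _dump_json(rows, out / "gsea.json")
        pd.DataFrame(rows).to_csv(out / "gsea.tsv", sep="\t", index=False)
        artifacts["gsea"] = str(out / "gsea.json")

    def do_lengths():
        rows = {}
        for tissue, path in sorted(config.deg_tables.items()):
            table = kio.read_deg(_require(path, f"DEG table ({tissue})"))
            r = length_imbalance(table)
            rows[tissue] = {
                "median_up": r.median_up, "median_down": r.median_down,
                "pvalue": r.pvalue, "direction": r.direction,
                "n_up": r.n_up, "n_down": r.n_down,
            }
        _dump_json(rows, out / "lengths.json")
        artifacts["lengths"] = str(out / "lengths.json")

    def do_signature():
        per_tissue = {}
        for tissue, path in sorted(config.deg_tables.items()):
            table = kio.read_deg(_require(path, f"DEG table ({tissue})"))
            up, _ = call_degs(table)
            per_tissue[tissue] = up
        sig = core_signature(per_tissue)
        _dump_json(
            {
                "intersection": sig.intersection,
                "intersection_size": len(sig.intersection),
                "pairwise_overlap": {
                    f"{a}&{b}": v for (a, b), v in sig.pairwise_overlap.items()
                },
                "per_tissue_sizes": {t: len(s) for t, s in sig.per_tissue.items()},
            },
            out / "signature.json",
        )
        artifacts["signature"] = str(out / "signature.json")

    if config.deg_tables:
        if config.gmt is not None:
            stage("gsea", do_gsea)
        stage("lengths", do_lengths)
        if len(config.deg_tables) >= 2:
            stage("signature", do_signature)

    def do_immune():
        counts = kio.read_counts(_require(config.counts, "counts"))
        markers = kio.read_gmt(_require(config.marker_gmt, "marker GMT"))
        import numpy as np

        expr = np.log2(counts + 1)
        scores = immune_score(expr, markers)
        scores.to_csv(out / "immune.tsv", sep="\t", index_label="sample")
        artifacts["immune"] = str(out / "immune.tsv")

    if config.counts is not None and config.marker_gmt is not None:
        stage("immune", do_immune)

    _dump_json(
        {
            "package_version": __version__,
            "config_hash": config_hash,
            "seed": config.seed,
        },
        out / "meta.json",
    )
    artifacts["meta"] = str(out / "meta.json")
    return artifacts
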