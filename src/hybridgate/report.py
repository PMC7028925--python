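"""Evidence integration, uncertainty statistics and pipeline orchestration.

Auxiliary markers (mtDNA control-region haplotype, Y-linked STR haplotype,
the K-locus 3-bp melanistic deletion, dog-like phenotypic traits) carry
information about the *direction* and age of introgression but are treated
strictly as corroborating annotations: the q-based management category of an
individual is never changed by a flag.  An operational-pure individual
carrying a dog Y haplotype is reported as a possible older admixed animal,
nothing more.

`run_pipeline` wires the whole workflow together: synthetic reference
generation, hybrid-ladder simulation, optional error injection, one-by-one
Bayesian assignment, performance analysis, classification and reporting,
with a JSON manifest capturing seeds and configuration for reproducibility.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .admixture import (AssignmentResult, McmcConfig, align_clusters,
                        assign_one_by_one, results_to_frame,
                        run_admixture_mcmc, summarize_individual)
from .core_io import write_structure_table
from .errorsim import ErrorSpec, degrade
from .hybsim import build_class_ladder
from .synthref import DivergenceSpec, default_reference_fixture
from .thresholds import (CATEGORY_OF_CLASS, ThresholdPair, classify_table,
                         error_rates, performance_grid,
                         select_pure_threshold, select_recent_threshold)

logger = logging.getLogger("hybridgate")


@dataclass
class EvidenceFlags:
    """Auxiliary-marker evidence for one individual.

    ``dog_y_haplotype`` is None for females (no Y chromosome); supplying a
    Y flag for a female is a validation error.
    """

    individual_id: str
    dog_mtdna: bool = False
    dog_y_haplotype: bool | None = None
    k_locus_deletion: bool = False
    dog_like_phenotype: bool = False
    sex: str | None = None  # "M", "F" or unknown

    def __post_init__(self) -> None:
        if self.sex == "F" and self.dog_y_haplotype is not None:
            raise ValueError(
                f"{self.individual_id}: a female cannot carry a Y-haplotype flag"
            )


def _flags_frame(flags: list[EvidenceFlags] | pd.DataFrame | None) -> pd.DataFrame:
    if flags is None:
        return pd.DataFrame(columns=["individual_id", "dog_mtdna",
                                     "dog_y_haplotype", "k_locus_deletion",
                                     "dog_like_phenotype", "sex"])
    if isinstance(flags, pd.DataFrame):
        return flags.copy()
    return pd.DataFrame([asdict(f) for f in flags])


def integrate_evidence(
    classified: pd.DataFrame,
    flags: list[EvidenceFlags] | pd.DataFrame | None = None,
) -> dict:
    """Merge q-based categories with auxiliary-marker evidence.

    Returns a report dict with the per-individual table (categories plus
    flags plus an ``older_admixture_suspect`` annotation for pure-classified
    carriers of any dog-derived marker) and per-category cross-tabulated
    counts and percentages; Y-haplotype percentages use the male-only
    denominator.  Flags for unknown individuals are warned about and
    dropped, never fatal.
    """
    fl = _flags_frame(flags)
    known = set(classified["individual_id"])
    unknown = [i for i in fl.get("individual_id", []) if i not in known]
    if unknown:
        logger.warning("evidence flags for unknown individuals ignored: %s",
                       unknown[:5])
        fl = fl[fl["individual_id"].isin(known)]
    def as_bool(series: pd.Series) -> pd.Series:
        return series.map(lambda v: bool(v) if pd.notna(v) else False)

    merged = classified.merge(fl, on="individual_id", how="left")
    for col in ("dog_mtdna", "k_locus_deletion", "dog_like_phenotype"):
        merged[col] = as_bool(merged[col]) if col in merged else False
    if "dog_y_haplotype" not in merged:
        merged["dog_y_haplotype"] = None
    if "sex" not in merged:
        merged["sex"] = None

    merged["older_admixture_suspect"] = (
        (merged["management_category"] == "operational_pure")
        & (
            merged["dog_mtdna"]
            | as_bool(merged["dog_y_haplotype"])
            | merged["k_locus_deletion"]
        )
    )

    categories = list(CATEGORY_OF_CLASS.values())
    per_category = {}
    total = len(merged)
    for cat in categories:
        sub = merged[merged["management_category"] == cat]
        males = sub[sub["sex"] == "M"]
        n_males = len(males)
        y_carriers = int(as_bool(males["dog_y_haplotype"]).sum())
        per_category[cat] = {
            "n": int(len(sub)),
            "pct_of_total": round(100.0 * len(sub) / total, 1) if total else 0.0,
            "n_males": n_males,
            "dog_mtdna": int(sub["dog_mtdna"].sum()),
            "dog_y_haplotype": y_carriers,
            "dog_y_haplotype_pct_of_males":
                round(100.0 * y_carriers / n_males, 1) if n_males else 0.0,
            "k_locus_deletion": int(sub["k_locus_deletion"].sum()),
            "dog_like_phenotype": int(sub["dog_like_phenotype"].sum()),
        }
    return {"individuals": merged, "per_category": per_category}


def ci_width_statistics(
    results: list[AssignmentResult],
    group_pairs: list[tuple[tuple[str, ...], tuple[str, ...]]] | None = None,
) -> dict:
    """Relationship between posterior uncertainty and assignment strength.

    Computes the Pearson correlation between 90%-CI width and q_iw over all
    individuals (expected strongly negative: admixed individuals are the
    uncertain ones) and Welch t-tests comparing mean CI width between label
    groups (admixed vs. parental by default).
    """
    if len(results) < 3:
        raise ValueError("need at least 3 individuals")
    widths = np.array([r.ci_width for r in results])
    q = np.array([r.q_wild_mean for r in results])
    if np.ptp(widths) == 0 or np.ptp(q) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(q, widths)
    out = {"pearson_r": float(r), "pearson_p": float(p), "t_tests": {}}
    if group_pairs is None:
        group_pairs = [(("F1", "F2", "BC1W", "BC2W", "BC3W", "BC4W",
                         "BC5W", "BC6W", "BC7W", "BC8W"), ("PW", "RW"))]
    labels = np.array([res.label for res in results])
    for ga, gb in group_pairs:
        wa = widths[np.isin(labels, ga)]
        wb = widths[np.isin(labels, gb)]
        if len(wa) < 2 or len(wb) < 2:
            continue
        t, tp = stats.ttest_ind(wa, wb, equal_var=False)
        out["t_tests"][f"{'+'.join(ga)} vs {'+'.join(gb)}"] = {
            "t": float(t), "p": float(tp),
            "mean_width_a": float(wa.mean()), "mean_width_b": float(wb.mean()),
        }
    return out


@dataclass
class PipelineConfig:
    """Structured description of one end-to-end run."""

    seed: int = 0
    n_loci: int = 39
    alleles_per_locus: int = 8
    fst_target: float = 0.30
    n_wild: int = 100
    n_domestic: int = 95
    n_per_class: int = 100
    ladder_classes: tuple[str, ...] | None = None
    ado_rate: float = 0.0
    missing_rate: float = 0.0
    n_burnin: int = 5_000
    n_iter: int = 20_000
    thin: int = 10
    t_recent: float | None = None   # None -> derive from the performance grid
    t_pure: float | None = None     # None -> derive from wild parental minimum
    out_dir: str = "hybridgate_run"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write all artifacts under ``out_dir``.

    Stages: simulate-refs -> simulate-hybrids -> [inject-errors] -> assign
    (one-by-one) -> performance -> classify -> report.  Byte-identical
    outputs are guaranteed for identical (config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    try:
        stage = "simulate-refs"
        t0 = time.perf_counter()
        spec = DivergenceSpec(
            n_loci=config.n_loci, alleles_per_locus=config.alleles_per_locus,
            fst_target=config.fst_target, seed=config.seed,
        )
        freqs, refs = default_reference_fixture(
            config.seed, config.n_wild, config.n_domestic, spec=spec
        )
        write_structure_table(refs, out / "refs.str")
        timings[stage] = time.perf_counter() - t0
        logger.info("%s: %d references", stage, refs.n_individuals)

        stage = "simulate-hybrids"
        t0 = time.perf_counter()
        ladder = build_class_ladder(
            freqs, n_per_class=config.n_per_class, seed=config.seed,
            classes=config.ladder_classes,
        )
        write_structure_table(ladder, out / "ladder.str")
        timings[stage] = time.perf_counter() - t0
        logger.info("%s: %d simulated genotypes", stage, ladder.n_individuals)

        queries = ladder
        if config.ado_rate > 0 or config.missing_rate > 0:
            stage = "inject-errors"
            t0 = time.perf_counter()
            queries = degrade(ladder, ErrorSpec(
                config.ado_rate, config.missing_rate, config.seed))
            write_structure_table(queries, out / "ladder_degraded.str")
            timings[stage] = time.perf_counter() - t0
            logger.info("%s: ado=%.2f missing=%.2f", stage,
                        config.ado_rate, config.missing_rate)

        stage = "assign"
        t0 = time.perf_counter()
        mcmc = McmcConfig(n_burnin=config.n_burnin, n_iter=config.n_iter,
                          thin=config.thin, seed=config.seed)
        results = assign_one_by_one(refs, queries, mcmc)
        ref_run = align_clusters(run_admixture_mcmc(refs, mcmc))
        ref_results = [summarize_individual(ref_run, i)
                       for i in refs.individual_ids]
        q_table = results_to_frame(results + ref_results)
        q_table.to_csv(out / "q_table.csv", index=False)
        timings[stage] = time.perf_counter() - t0
        logger.info("%s: %d assignments", stage, len(q_table))

        stage = "performance"
        t0 = time.perf_counter()
        qv = q_table.rename(columns={"q_wild_mean": "q_wild"})
        grid = performance_grid(qv)
        grid.to_csv(out / "grid.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        if config.t_recent is not None and config.t_pure is not None:
            pair = ThresholdPair(config.t_recent, config.t_pure)
            derivation = "fixed"
        else:
            t_recent, _ = select_recent_threshold(grid)
            t_pure = select_pure_threshold(qv)
            pair = ThresholdPair(t_recent, t_pure)
            derivation = "derived"
        classes = classify_table(qv, pair)
        classes.to_csv(out / "classes.csv", index=False)
        timings[stage] = time.perf_counter() - t0
        logger.info("%s: thresholds %s (%s)", stage, pair, derivation)

        stage = "report"
        t0 = time.perf_counter()
        type_i, type_ii, confusion = error_rates(classes)
        confusion.to_csv(out / "confusion.csv")
        report = integrate_evidence(classes)
        ci_stats = ci_width_statistics(results + ref_results)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "thresholds": {"t_recent": pair.t_recent, "t_pure": pair.t_pure,
                           "derivation": derivation},
            "error_rates": {"type_i": type_i, "type_ii": type_ii},
            "ci_statistics": {k: v for k, v in ci_stats.items()},
            "per_category": report["per_category"],
            "timings_s": {k: round(v, 2) for k, v in timings.items()},
        }
        with open(out / "report.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {
        "thresholds": pair,
        "q_table": q_table,
        "grid": grid,
        "classes": classes,
        "confusion": confusion,
        "type_i": type_i,
        "type_ii": type_ii,
        "manifest": manifest,
        "out_dir": str(out),
    }
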