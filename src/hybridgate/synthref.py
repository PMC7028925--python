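"""Synthetic wild/domestic reference populations with controlled divergence.

Two parental gene pools are generated with a multiallelic Balding–Nichols
construction: per locus an ancestral frequency vector is drawn from a
symmetric Dirichlet, and each descendant population draws its own vector from
``Dirichlet(ancestral * (1 - F) / F)``, so that ``F`` plays the role of the
target FST between either population and the ancestor.  This gives one-knob
control over the wild/dog differentiation that drives every downstream
assignment result; genotypes are then sampled under Hardy–Weinberg
equilibrium with unlinked loci.

The realized differentiation of sampled populations can be validated with a
multi-locus Weir–Cockerham theta estimator (:func:`realized_fst`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AlleleFrequencySet, GenotypeTable, MarkerPanel, concat_tables

WILD = "wild"
DOMESTIC = "domestic"


@dataclass(frozen=True)
class DivergenceSpec:
    """Parameters of the synthetic parental pools.

    Defaults emulate two strongly differentiated populations typed at the
    full 39-locus microsatellite panel with 8 alleles per locus and F=0.30,
    which reproduces near-complete K=2 cluster separation of references.
    """

    n_loci: int = 39
    alleles_per_locus: int = 8
    fst_target: float = 0.30
    ancestral_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_target < 0.95:
            raise ValueError("fst_target must lie in (0, 0.95)")
        if self.alleles_per_locus < 2:
            raise ValueError("need at least 2 alleles per locus")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")


def draw_parental_frequencies(spec: DivergenceSpec) -> AlleleFrequencySet:
    """Draw wild and domestic allele frequencies under Balding–Nichols."""
    rng = np.random.default_rng(spec.seed)
    panel = MarkerPanel.default(spec.n_loci)
    A = spec.alleles_per_locus
    support = [np.arange(100, 100 + A, dtype=np.int64) for _ in range(spec.n_loci)]
    F = spec.fst_target
    scale = (1.0 - F) / F
    freqs: dict[str, list[np.ndarray]] = {WILD: [], DOMESTIC: []}
    for _ in range(spec.n_loci):
        ancestral = rng.dirichlet(np.full(A, spec.ancestral_concentration))
        # Keep the Dirichlet parameters strictly positive even when the
        # ancestral draw has near-zero components.
        alpha = np.maximum(ancestral * scale, 1e-9)
        for pop in (WILD, DOMESTIC):
            v = rng.dirichlet(alpha)
            v = v / v.sum()
            freqs[pop].append(v)
    return AlleleFrequencySet((WILD, DOMESTIC), panel, support, freqs)


def sample_reference_population(
    freqs: AlleleFrequencySet, population: str, n: int, seed: int,
    label: str | None = None, id_prefix: str | None = None,
) -> GenotypeTable:
    """Sample ``n`` Hardy–Weinberg genotypes from one population's frequencies."""
    if population not in freqs.populations:
        raise KeyError(f"unknown population {population!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = freqs.n_loci
    alleles = np.empty((n, L, 2), dtype=np.int32)
    for l in range(L):
        p = freqs.freqs[population][l]
        draws = rng.choice(freqs.support[l], size=(n, 2), p=p)
        alleles[:, l, :] = draws
    label = label or population
    id_prefix = id_prefix or label
    ids = [f"{id_prefix}_{i + 1:04d}" for i in range(n)]
    return GenotypeTable(ids, [label] * n, alleles, freqs.panel)


def _wc_theta_components(tableA: GenotypeTable, tableB: GenotypeTable):
    """Per-locus Weir–Cockerham (1984) variance components, summed over alleles."""
    if tableA.panel.locus_names != tableB.panel.locus_names:
        raise ValueError("tables must share a panel")
    r = 2.0  # two populations
    num_sum = 0.0
    den_sum = 0.0
    informative = 0
    for l in range(tableA.n_loci):
        pops = []
        for t in (tableA, tableB):
            g = t.alleles[:, l, :]
            keep = g[:, 0] != -9
            g = g[keep]
            if len(g) == 0:
                pops = []
                break
            pops.append(g)
        if not pops:
            continue
        alleles = np.unique(np.concatenate([g.ravel() for g in pops]))
        if len(alleles) < 2:
            continue
        n_i = np.array([len(g) for g in pops], dtype=float)
        n_bar = n_i.mean()
        n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
        for a in alleles:
            p_i = np.array([(g == a).mean() for g in pops])
            h_i = np.array([((g[:, 0] == a) ^ (g[:, 1] == a)).mean() for g in pops])
            p_bar = (n_i * p_i).sum() / n_i.sum()
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i).sum() / n_i.sum()
            a_comp = (n_bar / n_c) * (
                s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b_comp = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c_comp = h_bar / 2
            num_sum += a_comp
            den_sum += a_comp + b_comp + c_comp
        informative += 1
    if informative == 0 or den_sum == 0.0:
        raise ValueError("no shared polymorphic loci between the tables")
    return num_sum, den_sum


def realized_fst(tableA: GenotypeTable, tableB: GenotypeTable) -> float:
    """Multi-locus Weir–Cockerham theta between two genotype samples."""
    num, den = _wc_theta_components(tableA, tableB)
    return num / den


def default_reference_fixture(
    seed: int,
    n_wild: int = 100,
    n_domestic: int = 95,
    spec: DivergenceSpec | None = None,
) -> tuple[AlleleFrequencySet, GenotypeTable]:
    """Convenience: frequencies plus a combined RW+RD reference table.

    Sample sizes default to 100 wolves / 95 dogs — comfortably above the
    ~40-individuals-per-pool floor usually recommended for reference
    populations in admixture assignment.
    """
    if spec is None:
        spec = DivergenceSpec(seed=seed)
    freqs = draw_parental_frequencies(spec)
    ss = np.random.SeedSequence([seed, 71])
    s_w, s_d = (int(s) for s in ss.generate_state(2) % (2 ** 31))
    wolves = sample_reference_population(freqs, WILD, n_wild, s_w, label="RW")
    dogs = sample_reference_population(freqs, DOMESTIC, n_domestic, s_d, label="RD")
    return freqs, concat_tables([wolves, dogs])
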