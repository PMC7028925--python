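"""Hybrid-class genotype simulation by Mendelian gamete sampling.

Builds the ladder of admixture classes used throughout the workflow: pure
wild and domestic parentals (PW, PD), first- and second-generation hybrids
(F1, F2) and eight successive backcrosses toward the wild pool (BC1W-BC8W).
Parental gametes are drawn directly from the population allele-frequency
pools; gametes of later generations are drawn from simulated individuals'
genotypes (one allele chosen at random per locus — Mendelian segregation with
unlinked loci), which preserves the within-individual ancestry correlation
that drives the variance of admixture coefficients among backcrosses.

Selectively neutral throughout: no linkage, mutation or selection, so the
expected domestic ancestry of BCnW is exactly 0.5**(n+1) (BC8W retains less
than 0.2% domestic ancestry in expectation).
"""

from __future__ import annotations

import re

import numpy as np

from .core_io import AlleleFrequencySet, GenotypeTable, concat_tables
from .synthref import DOMESTIC, WILD

#: Ladder order from pure domestic ancestry down to pure wild.
LADDER_CLASSES = (
    "PD", "F1", "F2", "BC1W", "BC2W", "BC3W", "BC4W",
    "BC5W", "BC6W", "BC7W", "BC8W", "PW",
)


def expected_domestic_ancestry(class_name: str) -> float:
    """Neutral pedigree expectation of domestic ancestry for a ladder class."""
    if class_name == "PW":
        return 0.0
    if class_name == "PD":
        return 1.0
    if class_name in ("F1", "F2"):
        return 0.5
    m = re.fullmatch(r"BC([1-8])W", class_name)
    if m:
        return 0.5 ** (int(m.group(1)) + 1)
    raise KeyError(f"unknown admixture class {class_name!r}")


def _freq_gametes(
    freqs: AlleleFrequencySet, population: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, n_loci) haploid gametes drawn from a population frequency pool."""
    L = freqs.n_loci
    out = np.empty((n, L), dtype=np.int32)
    for l in range(L):
        out[:, l] = rng.choice(freqs.support[l], size=n, p=freqs.freqs[population][l])
    return out


def _genotype_gametes(pool: GenotypeTable, n: int, rng: np.random.Generator) -> np.ndarray:
    """Gametes from a genotype pool: per offspring pick a random parent, then
    per locus pass one of its two alleles at random (loci independent)."""
    if pool.n_individuals == 0:
        raise ValueError("empty genotype pool")
    if pool.missing_mask().any():
        raise ValueError("gamete pools must not contain missing genotypes")
    parents = rng.integers(0, pool.n_individuals, size=n)
    which = rng.integers(0, 2, size=(n, pool.n_loci))
    loci = np.broadcast_to(np.arange(pool.n_loci), (n, pool.n_loci))
    return pool.alleles[parents[:, None], loci, which].astype(np.int32)


def simulate_parentals(
    freqs: AlleleFrequencySet, class_name: str, n: int, seed: int
) -> GenotypeTable:
    """Simulate PW or PD parental genotypes by Hardy–Weinberg draws."""
    pool = {"PW": WILD, "PD": DOMESTIC}.get(class_name)
    if pool is None:
        raise KeyError("parental class must be 'PW' or 'PD'")
    if pool not in freqs.populations:
        raise KeyError(f"frequency set lacks the {pool!r} pool")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    g1 = _freq_gametes(freqs, pool, n, rng)
    g2 = _freq_gametes(freqs, pool, n, rng)
    alleles = np.stack([g1, g2], axis=2)
    ids = [f"{class_name}_{i + 1:04d}" for i in range(n)]
    return GenotypeTable(ids, [class_name] * n, alleles, freqs.panel)


def simulate_cross(
    parent_pool_a: GenotypeTable | tuple[AlleleFrequencySet, str],
    parent_pool_b: GenotypeTable | tuple[AlleleFrequencySet, str],
    class_name: str,
    n: int,
    seed: int,
) -> GenotypeTable:
    """Cross two parental pools; each offspring gets one gamete from each side.

    A pool is either a GenotypeTable (gametes by Mendelian segregation from a
    random individual) or a ``(AlleleFrequencySet, population)`` pair (gametes
    drawn from the frequency vector, as for parental populations).
    """
    rng = np.random.default_rng(seed)

    def gametes(pool, n):
        if isinstance(pool, GenotypeTable):
            return _genotype_gametes(pool, n, rng)
        freqs, population = pool
        return _freq_gametes(freqs, population, n, rng)

    ga = gametes(parent_pool_a, n)
    gb = gametes(parent_pool_b, n)
    alleles = np.stack([ga, gb], axis=2)
    panel = (
        parent_pool_a.panel
        if isinstance(parent_pool_a, GenotypeTable)
        else parent_pool_a[0].panel
    )
    ids = [f"{class_name}_{i + 1:04d}" for i in range(n)]
    return GenotypeTable(ids, [class_name] * n, alleles, panel)


def build_class_ladder(
    freqs: AlleleFrequencySet,
    n_per_class: int = 100,
    seed: int = 0,
    classes: tuple[str, ...] | None = None,
) -> GenotypeTable:
    """Simulate the full 12-class ladder (or a subset) and concatenate it.

    F1 = PW-pool x PD-pool, F2 = F1 x F1, BC1W = F1 x wild pool, and
    BCkW = BC(k-1)W x wild pool; the wild gamete of every backcross comes
    from the wolf frequency pool.  ``n_per_class=100`` gives the standard
    1,200-genotype simulated dataset.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 individuals per class")
    wanted = LADDER_CLASSES if classes is None else tuple(classes)
    unknown = [c for c in wanted if c not in LADDER_CLASSES]
    if unknown:
        raise KeyError(f"unknown ladder classes: {unknown}")
    seeds = {
        name: int(s)
        for name, s in zip(
            LADDER_CLASSES,
            np.random.SeedSequence([seed, 1207]).generate_state(len(LADDER_CLASSES))
            % (2 ** 31),
        )
    }
    tables: dict[str, GenotypeTable] = {}
    tables["PW"] = simulate_parentals(freqs, "PW", n_per_class, seeds["PW"])
    tables["PD"] = simulate_parentals(freqs, "PD", n_per_class, seeds["PD"])
    tables["F1"] = simulate_cross(
        (freqs, WILD), (freqs, DOMESTIC), "F1", n_per_class, seeds["F1"]
    )
    tables["F2"] = simulate_cross(tables["F1"], tables["F1"], "F2",
                                  n_per_class, seeds["F2"])
    prev = tables["F1"]
    for k in range(1, 9):
        name = f"BC{k}W"
        tables[name] = simulate_cross(prev, (freqs, WILD), name,
                                      n_per_class, seeds[name])
        prev = tables[name]
    return concat_tables([tables[c] for c in wanted])
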