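"""Hybrid genotype-frequency-class MCMC (NewHybrids-type model).

Whereas the admixture model estimates a continuous ancestry proportion, this
model assigns each individual to one of a small set of discrete hybrid
classes defined by their expected *genotype frequency class* vector
``g = (g0, g1, g2)``: the probability that a random locus carries (two
wild-origin copies, one of each origin, two domestic-origin copies).  The
five classes used here are the two parentals, F1, F2 and the first wild
backcross:

====== =================
class  g = (g0, g1, g2)
====== =================
PW     (1, 0, 0)
PD     (0, 0, 1)
F1     (0, 1, 0)
F2     (1/4, 1/2, 1/4)
BC1W   (1/2, 1/2, 0)
====== =================

The Gibbs sampler alternates: per-individual class ``z_i`` (marginalising
the per-locus origin states), per-locus origin state ``w_il in {0,1,2}``,
latent allele origins within mixed-origin loci, population allele
frequencies (Dirichlet) and class mixing proportions (Dirichlet).  Two prior
flavours are supported: "jeffreys" (concentration 1/(number of alleles at
the locus), 1/(number of classes)) and "uniform" (all concentrations 1).
No individual carries any prior class or population information; the
wild/domestic orientation of the two latent populations is anchored only by
initialising reference-labelled individuals in their parental classes.

Classes older than BC1W are deliberately not modelled: with this class set
older backcrosses get absorbed into PW or BC1W, which is a documented
property of the model, and extending the class list does not rescue it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import MISSING, GenotypeTable

CLASS_NAMES = ("PW", "PD", "F1", "F2", "BC1W")

#: Genotype-frequency-class vectors, rows in CLASS_NAMES order, columns =
#: (both copies wild, one of each, both domestic).
G_VECTORS = np.array([
    [1.00, 0.00, 0.00],   # PW
    [0.00, 0.00, 1.00],   # PD
    [0.00, 1.00, 0.00],   # F1
    [0.25, 0.50, 0.25],   # F2
    [0.50, 0.50, 0.00],   # BC1W
])


@dataclass(frozen=True)
class GenotypeClassSpec:
    class_names: tuple[str, ...]
    g: np.ndarray

    def g_of(self, name: str) -> tuple[float, float, float]:
        return tuple(self.g[self.class_names.index(name)])


def class_g_vectors() -> GenotypeClassSpec:
    """The fixed five-class genotype-frequency table (Mendelian expectations)."""
    return GenotypeClassSpec(CLASS_NAMES, G_VECTORS.copy())


@dataclass
class ClassPosterior:
    individual_id: str
    label: str
    probs: dict[str, float]

    @property
    def map_class(self) -> str:
        return max(self.probs, key=self.probs.get)

    def prob(self, name: str) -> float:
        return self.probs[name]


@dataclass(frozen=True)
class GenoclassConfig:
    """Desk-scale default chain: 2e3 burn-in + 1e4 sweeps."""

    n_burnin: int = 2_000
    n_iter: int = 10_000
    seed: int = 0


# ---------------------------------------------------------------------------

def _encode(table: GenotypeTable):
    n, L, _ = table.alleles.shape
    support = [
        np.unique(col[col != MISSING])
        for col in (table.alleles[:, l, :].ravel() for l in range(L))
    ]
    n_alleles = np.array([len(s) for s in support])
    max_a = int(n_alleles.max())
    X = np.full((n, L, 2), -1, dtype=np.int64)
    for l in range(L):
        lookup = {int(a): j for j, a in enumerate(support[l])}
        for c in range(2):
            col = table.alleles[:, l, c]
            for i in np.flatnonzero(col != MISSING):
                X[i, l, c] = lookup[int(col[i])]
    return X, n_alleles, max_a


def _locus_likelihoods(P: np.ndarray, a, b, het, valid) -> np.ndarray:
    """(n, L, 3) likelihood of each observed locus call under each origin state."""
    L = P.shape[1]
    cols = np.arange(L)[None, :]
    a_ = np.where(valid, a, 0)
    b_ = np.where(valid, b, 0)
    p0a = P[0][cols, a_]
    p0b = P[0][cols, b_]
    p1a = P[1][cols, a_]
    p1b = P[1][cols, b_]
    lw = np.empty(a.shape + (3,))
    lw[:, :, 0] = np.where(het, 2.0 * p0a * p0b, p0a * p0a)
    lw[:, :, 1] = np.where(het, p0a * p1b + p0b * p1a, p0a * p1a)
    lw[:, :, 2] = np.where(het, 2.0 * p1a * p1b, p1a * p1a)
    lw[~valid] = 1.0  # missing loci carry no information
    return np.clip(lw, 1e-300, None)


def run_genoclass_mcmc(
    table: GenotypeTable,
    prior: str = "jeffreys",
    config: GenoclassConfig | None = None,
) -> list[ClassPosterior]:
    """Posterior class probabilities for every individual in the table.

    The table should mix the two reference pools and the individuals to be
    classified: allele frequencies of the latent wild and domestic
    populations are estimated jointly from everyone, with no individual
    priors.
    """
    if table.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if prior not in ("jeffreys", "uniform"):
        raise ValueError("prior must be 'jeffreys' or 'uniform'")
    cfg = config or GenoclassConfig()
    rng = np.random.default_rng(cfg.seed)
    X, n_alleles, max_a = _encode(table)
    n, L, _ = X.shape
    C = len(CLASS_NAMES)
    g = G_VECTORS

    a, b = X[:, :, 0], X[:, :, 1]
    valid = a >= 0
    het = valid & (a != b)

    if prior == "jeffreys":
        freq_prior = np.zeros((L, max_a))
        for l in range(L):
            freq_prior[l, : n_alleles[l]] = 1.0 / n_alleles[l]
        pi_prior = np.full(C, 1.0 / C)
    else:
        freq_prior = np.zeros((L, max_a))
        for l in range(L):
            freq_prior[l, : n_alleles[l]] = 1.0
        pi_prior = np.ones(C)

    # init: P from pooled counts, pi flat, z anchored by recognisable labels
    counts0 = np.zeros((L, max_a))
    for l in range(L):
        obs = X[:, l, :][X[:, l, :] >= 0]
        counts0[l, : n_alleles[l]] = np.bincount(obs, minlength=n_alleles[l])
    pooled = counts0 + freq_prior
    pooled /= pooled.sum(axis=1, keepdims=True)
    P = np.stack([pooled.copy(), pooled.copy()])
    pi = np.full(C, 1.0 / C)
    z = rng.integers(0, C, size=n)
    labels = np.asarray(table.labels)
    z[np.isin(labels, ("RW", "PW"))] = CLASS_NAMES.index("PW")
    z[np.isin(labels, ("RD", "PD"))] = CLASS_NAMES.index("PD")

    cols = np.arange(L)[None, :]
    occupancy = np.zeros((n, C))
    support_mask = np.zeros((L, max_a), dtype=bool)
    for l in range(L):
        support_mask[l, : n_alleles[l]] = True

    total = cfg.n_burnin + cfg.n_iter
    for sweep in range(total):
        lw = _locus_likelihoods(P, a, b, het, valid)

        # --- class z_i | pi, P (marginal over w) ---
        mix = lw @ g.T                     # (n, L, C)
        loglik = np.log(np.clip(mix, 1e-300, None)).sum(axis=1)
        logp = loglik + np.log(pi)
        gumbel = -np.log(-np.log(rng.random((n, C))))
        z = np.argmax(logp + gumbel, axis=1)

        # --- origin state w_il | z, P ---
        wprob = g[z][:, None, :] * lw      # (n, L, 3)
        wprob /= wprob.sum(axis=2, keepdims=True)
        u = rng.random((n, L))
        cum = np.cumsum(wprob, axis=2)
        w = (u[:, :, None] > cum).sum(axis=2)

        # --- allele-origin counts (missing loci excluded) ---
        counts = np.zeros((2, L, max_a))
        flat_l = np.broadcast_to(cols, (n, L))
        for state, pop_a, pop_b in ((0, 0, 0), (2, 1, 1)):
            sel = valid & (w == state)
            np.add.at(counts[pop_a], (flat_l[sel], a[sel]), 1.0)
            np.add.at(counts[pop_b], (flat_l[sel], b[sel]), 1.0)
        sel = valid & (w == 1)
        if sel.any():
            p0a = P[0][cols, np.where(valid, a, 0)]
            p0b = P[0][cols, np.where(valid, b, 0)]
            p1a = P[1][cols, np.where(valid, a, 0)]
            p1b = P[1][cols, np.where(valid, b, 0)]
            # orientation: did allele `a` come from the wild population?
            pa_wild = p0a * p1b / np.clip(p0a * p1b + p0b * p1a, 1e-300, None)
            a_wild = rng.random((n, L)) < pa_wild
            hsel = sel & het
            for wild_is_a in (True, False):
                s = hsel & (a_wild == wild_is_a)
                first, second = (a, b) if wild_is_a else (b, a)
                np.add.at(counts[0], (flat_l[s], first[s]), 1.0)
                np.add.at(counts[1], (flat_l[s], second[s]), 1.0)
            homsel = sel & ~het
            np.add.at(counts[0], (flat_l[homsel], a[homsel]), 1.0)
            np.add.at(counts[1], (flat_l[homsel], b[homsel]), 1.0)

        # --- P | counts ---
        gam = rng.gamma(np.where(support_mask[None], freq_prior[None] + counts, 0.0) + 1e-300)
        gam *= support_mask[None]
        P = gam / np.clip(gam.sum(axis=2, keepdims=True), 1e-300, None)
        P = np.clip(P, 1e-12, None)
        P *= support_mask[None]
        P /= P.sum(axis=2, keepdims=True)

        # --- pi | z ---
        zc = np.bincount(z, minlength=C)
        gpi = rng.gamma(pi_prior + zc)
        pi = gpi / gpi.sum()

        if sweep >= cfg.n_burnin:
            occupancy[np.arange(n), z] += 1.0

    post = occupancy / cfg.n_iter

    # resolve the residual wild/domestic orientation symmetry post hoc
    anchor = np.isin(labels, ("RW", "PW"))
    if anchor.any():
        ipw, ipd = CLASS_NAMES.index("PW"), CLASS_NAMES.index("PD")
        if post[anchor, ipd].mean() > post[anchor, ipw].mean():
            post[:, [ipw, ipd]] = post[:, [ipd, ipw]]

    return [
        ClassPosterior(
            individual_id=table.individual_ids[i],
            label=table.labels[i],
            probs={name: float(post[i, c]) for c, name in enumerate(CLASS_NAMES)},
        )
        for i in range(n)
    ]


def closed_form_class_posterior(
    freq_wild: list[np.ndarray],
    freq_dom: list[np.ndarray],
    genotype: np.ndarray,
    prior: np.ndarray | None = None,
) -> np.ndarray:
    """Exact class posterior at *known* allele frequencies (no MCMC).

    ``genotype`` is an (L, 2) array of support indices (missing = -1).  This
    is the analytic reference the sampler is checked against when
    frequencies are effectively known (e.g. fixed reference pools).
    """
    if prior is None:
        prior = np.full(len(CLASS_NAMES), 1.0 / len(CLASS_NAMES))
    loglik = np.zeros(len(CLASS_NAMES))
    for l, (pa, pb) in enumerate(genotype):
        if pa < 0:
            continue
        p0a, p0b = freq_wild[l][pa], freq_wild[l][pb]
        p1a, p1b = freq_dom[l][pa], freq_dom[l][pb]
        if pa == pb:
            lw = np.array([p0a * p0a, p0a * p1a, p1a * p1a])
        else:
            lw = np.array([2 * p0a * p0b, p0a * p1b + p0b * p1a, 2 * p1a * p1b])
        loglik += np.log(np.clip(G_VECTORS @ lw, 1e-300, None))
    logpost = loglik + np.log(prior)
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def compare_method_agreement(
    struct_counts: np.ndarray | list[int],
    genoclass_counts: np.ndarray | list[int],
) -> tuple[float, float]:
    """Pearson chi-square comparing two per-category count vectors.

    Categories with zero total across both methods are collapsed out before
    testing.  Returns (chi2, p).
    """
    x = np.asarray(struct_counts, dtype=float)
    y = np.asarray(genoclass_counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must be aligned")
    keep = (x + y) > 0
    tab = np.stack([x[keep], y[keep]])
    if tab.shape[1] < 2:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)
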