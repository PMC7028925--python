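"""Genotype data model and I/O for multilocus codominant marker tables.

The central container is :class:`GenotypeTable`: diploid genotypes at a panel
of unlinked codominant loci (microsatellites in the motivating use case), one
unordered pair of integer allele codes per individual per locus, with ``-9``
marking a missing locus (both copies missing together, as in standard
microsatellite scoring).  Files use a fixed Structure-dialect layout: one row
per individual holding the individual ID, a class/population label, then two
whitespace-separated allele columns per locus (ONEROWPERIND).

Allele codes are treated as opaque categorical labels; no repeat-length
arithmetic is ever performed on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel allele code for a missing locus call (both copies).
MISSING = -9

#: Labels used throughout the workflow: reference wild/domestic (RW, RD),
#: simulated parentals (PW, PD), hybrids (F1, F2), wild-direction backcrosses
#: (BC1W..BC8W) and unclassified queries.
DEFAULT_LABELS = (
    "RW", "RD", "PW", "PD", "F1", "F2",
    "BC1W", "BC2W", "BC3W", "BC4W", "BC5W", "BC6W", "BC7W", "BC8W",
    "QUERY",
)


class StructureParseError(ValueError):
    """Raised when a genotype file does not conform to the declared dialect."""


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered set of locus names (e.g. the 39-STR or reduced 12-STR panel)."""

    locus_names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.locus_names)
        object.__setattr__(self, "locus_names", names)
        if len(names) < 1:
            raise ValueError("a panel needs at least one locus")
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def index_of(self, name: str) -> int:
        try:
            return self.locus_names.index(name)
        except ValueError:
            raise KeyError(f"unknown locus {name!r}") from None

    @classmethod
    def default(cls, n_loci: int, prefix: str = "L") -> "MarkerPanel":
        return cls(tuple(f"{prefix}{i + 1:02d}" for i in range(n_loci)))


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes for a set of labelled individuals.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)``; a missing locus call
    is ``(-9, -9)``.  Row order is meaningful and preserved by every
    operation in this module.
    """

    individual_ids: list[str]
    labels: list[str]
    alleles: np.ndarray
    panel: MarkerPanel

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        n, L, _ = self.alleles.shape
        if len(self.individual_ids) != n or len(self.labels) != n:
            raise ValueError("ids/labels length must match allele array")
        if L != self.panel.n_loci:
            raise ValueError("allele array width must match the panel")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        bad = (self.alleles <= 0) & (self.alleles != MISSING)
        if bad.any():
            raise ValueError("allele codes must be positive integers or -9")
        half_missing = (self.alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("both allele copies of a locus must be missing together")

    # -- basic introspection ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the locus call is missing."""
        return self.alleles[:, :, 0] == MISSING

    def missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    # -- row/column selection ----------------------------------------------

    def take(self, rows: np.ndarray | list[int]) -> "GenotypeTable":
        rows = np.asarray(rows, dtype=int)
        return GenotypeTable(
            [self.individual_ids[i] for i in rows],
            [self.labels[i] for i in rows],
            self.alleles[rows].copy(),
            self.panel,
        )

    def with_labels(self, label: str) -> "GenotypeTable":
        return GenotypeTable(
            list(self.individual_ids), [label] * self.n_individuals,
            self.alleles.copy(), self.panel,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {"individual_id": self.individual_ids,
                                   "label": self.labels}
        for j, name in enumerate(self.panel.locus_names):
            cols[f"{name}.1"] = self.alleles[:, j, 0]
            cols[f"{name}.2"] = self.alleles[:, j, 1]
        return pd.DataFrame(cols)


def concat_tables(tables: list[GenotypeTable]) -> GenotypeTable:
    """Stack tables that share a panel, preserving order."""
    if not tables:
        raise ValueError("nothing to concatenate")
    panel = tables[0].panel
    for t in tables[1:]:
        if t.panel.locus_names != panel.locus_names:
            raise ValueError("tables use different panels")
    return GenotypeTable(
        sum((t.individual_ids for t in tables), []),
        sum((t.labels for t in tables), []),
        np.concatenate([t.alleles for t in tables], axis=0),
        panel,
    )


# ---------------------------------------------------------------------------
# File I/O (Structure ONEROWPERIND dialect)
# ---------------------------------------------------------------------------

def read_structure_table(path, panel: MarkerPanel) -> GenotypeTable:
    """Parse a whitespace-delimited genotype file against ``panel``.

    Each non-blank row: ``ID LABEL a1_1 a1_2 a2_1 a2_2 ...`` with two allele
    columns per panel locus.  Missing locus = ``-9 -9``.
    """
    ids: list[str] = []
    labels: list[str] = []
    rows: list[list[int]] = []
    want = 2 + 2 * panel.n_loci
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != want:
                raise StructureParseError(
                    f"{path}:{lineno}: expected {want} columns "
                    f"({panel.n_loci} loci), found {len(parts)}"
                )
            try:
                codes = [int(p) for p in parts[2:]]
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}:{lineno}: non-integer allele code ({exc})"
                ) from None
            ids.append(parts[0])
            labels.append(parts[1])
            rows.append(codes)
    alleles = (
        np.asarray(rows, dtype=np.int32).reshape(len(rows), panel.n_loci, 2)
        if rows else np.empty((0, panel.n_loci, 2), dtype=np.int32)
    )
    return GenotypeTable(ids, labels, alleles, panel)


def write_structure_table(table: GenotypeTable, path) -> None:
    """Write ``table`` in the same dialect read by :func:`read_structure_table`."""
    with open(path, "w") as fh:
        flat = table.alleles.reshape(table.n_individuals, 2 * table.n_loci)
        for i in range(table.n_individuals):
            cells = " ".join(str(int(a)) for a in flat[i])
            fh.write(f"{table.individual_ids[i]} {table.labels[i]} {cells}\n")


def read_evidence_flags(path) -> pd.DataFrame:
    """Read the auxiliary-marker evidence table (CSV).

    Columns: ``individual_id``, ``dog_mtdna`` (0/1), ``dog_y_haplotype``
    (0/1, empty for females), ``k_locus_deletion`` (0/1) and optionally
    ``dog_like_phenotype`` (0/1).
    """
    df = pd.read_csv(path, dtype={"individual_id": str})
    required = {"individual_id", "dog_mtdna", "dog_y_haplotype", "k_locus_deletion"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"evidence table lacks columns: {sorted(missing_cols)}")
    return df


# ---------------------------------------------------------------------------
# Panel subsetting and filters
# ---------------------------------------------------------------------------

def subset_panel(table: GenotypeTable, keep: list[str]) -> GenotypeTable:
    """Restrict (and reorder) the table to the loci named in ``keep``."""
    unknown = [k for k in keep if k not in table.panel.locus_names]
    if unknown:
        raise KeyError(f"unknown loci: {unknown}")
    idx = [table.panel.index_of(k) for k in keep]
    return GenotypeTable(
        list(table.individual_ids), list(table.labels),
        table.alleles[:, idx, :].copy(), MarkerPanel(tuple(keep)),
    )


def qc_filter_genotypes(table: GenotypeTable, max_missing_fraction: float) -> GenotypeTable:
    """Keep individuals whose missing-locus fraction is strictly below the cap.

    Mirrors the genotype-reliability rule of accepting a multilocus genotype
    only when missing data stay under 10% (``max_missing_fraction=0.10``).
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    keep = np.flatnonzero(table.missing_fraction() < max_missing_fraction)
    return table.take(keep)


def filter_reference_candidates(
    table: GenotypeTable,
    q_values: dict[str, float] | pd.Series,
    min_q: float = 0.990,
) -> GenotypeTable:
    """Apply the reference-selection rule: no missing loci AND q above ``min_q``.

    ``q_values`` maps each individual id to its membership proportion to its
    own nominal (wild or domestic) cluster, e.g. from a previous assignment
    run.  The default 0.990 is deliberately conservative so that older
    admixed animals are kept out of the reference pools.
    """
    if isinstance(q_values, pd.Series):
        q_values = q_values.to_dict()
    if not 0.5 < min_q <= 1.0:
        raise ValueError("min_q must be in (0.5, 1]")
    missing_q = [i for i in table.individual_ids if i not in q_values]
    if missing_q:
        raise KeyError(f"no q value for individuals: {missing_q[:5]}")
    complete = ~table.missing_mask().any(axis=1)
    q = np.array([q_values[i] for i in table.individual_ids])
    return table.take(np.flatnonzero(complete & (q > min_q)))


# ---------------------------------------------------------------------------
# Allele frequency estimation
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencySet:
    """Per-population, per-locus allele frequency vectors on a shared support.

    ``support[l]`` is the sorted array of allele codes observed at locus ``l``
    across *all* populations (harmonised support); ``freqs[pop][l]`` is the
    matching frequency vector, summing to 1.  Populations may have zero
    frequency at alleles observed only elsewhere.
    """

    populations: tuple[str, ...]
    panel: MarkerPanel
    support: list[np.ndarray]
    freqs: dict[str, list[np.ndarray]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.support) != self.panel.n_loci:
            raise ValueError("support length must match the panel")
        for pop in self.populations:
            vecs = self.freqs[pop]
            for l, v in enumerate(vecs):
                v = np.asarray(v, dtype=float)
                vecs[l] = v
                if v.shape != self.support[l].shape:
                    raise ValueError(f"support mismatch at locus {l} for {pop}")
                if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"frequencies at locus {l} for {pop} are not a simplex"
                    )

    @property
    def n_loci(self) -> int:
        return self.panel.n_loci

    def n_alleles(self, locus: int) -> int:
        return len(self.support[locus])

    def allele_index(self, locus: int) -> dict[int, int]:
        return {int(a): j for j, a in enumerate(self.support[locus])}

    def freq_matrix(self, pop: str, max_alleles: int | None = None) -> np.ndarray:
        """Dense (n_loci, max_alleles) matrix, zero-padded past each support."""
        if max_alleles is None:
            max_alleles = max(len(s) for s in self.support)
        out = np.zeros((self.n_loci, max_alleles))
        for l, v in enumerate(self.freqs[pop]):
            out[l, : len(v)] = v
        return out


def estimate_allele_frequencies(
    table: GenotypeTable, by_label: dict[str, list[str]] | None = None
) -> AlleleFrequencySet:
    """Sample allele frequencies per group by plain counting of non-missing copies.

    ``by_label`` maps a group name to the table labels it pools (default: one
    group per distinct label).  The allele support at each locus is harmonised
    to the union of alleles observed in any group, with zero frequency where a
    group never shows an allele.
    """
    if by_label is None:
        by_label = {lab: [lab] for lab in dict.fromkeys(table.labels)}
    labels = np.asarray(table.labels)
    support = [
        np.unique(col[col != MISSING])
        for col in (table.alleles[:, l, :].ravel() for l in range(table.n_loci))
    ]
    freqs: dict[str, list[np.ndarray]] = {}
    for group, members in by_label.items():
        rows = np.isin(labels, members)
        if not rows.any():
            raise ValueError(f"group {group!r} matches no individuals")
        vecs = []
        for l in range(table.n_loci):
            copies = table.alleles[rows, l, :].ravel()
            copies = copies[copies != MISSING]
            if copies.size == 0:
                raise ValueError(
                    f"locus {table.panel.locus_names[l]!r} has no non-missing "
                    f"copies in group {group!r}"
                )
            counts = np.array([(copies == a).sum() for a in support[l]], dtype=float)
            vecs.append(counts / counts.sum())
        freqs[group] = vecs
    return AlleleFrequencySet(tuple(by_label), table.panel, support, freqs)


def encode_alleles(table: GenotypeTable, afs: AlleleFrequencySet) -> np.ndarray:
    """Map allele codes to per-locus support indices; missing -> -1.

    Alleles absent from the support raise, guaranteeing downstream samplers
    only ever see indices valid for the frequency matrices.
    """
    out = np.full(table.alleles.shape, -1, dtype=np.int32)
    for l in range(table.n_loci):
        lookup = afs.allele_index(l)
        col = table.alleles[:, l, :]
        for (i, c), code in np.ndenumerate(col):
            if code == MISSING:
                continue
            try:
                out[i, l, c] = lookup[int(code)]
            except KeyError:
                raise ValueError(
                    f"allele {code} at locus {table.panel.locus_names[l]!r} "
                    "is outside the frequency-set support"
                ) from None
    return out
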