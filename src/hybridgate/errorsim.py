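"""Genotyping-error injection and assignment-robustness metrics.

Emulates the two error processes that dominate low-template microsatellite
genotyping: allelic dropout (ADO — one allele of a heterozygote fails to
amplify, producing a false homozygote) and missing locus calls.  The fixed
composition order is ADO first, then missingness, so a dropped-out call can
still go missing.  ADO is applied per heterozygous locus call; missingness
per locus call; the same nominal rate (10/20/30%) is conventionally applied
to both processes simultaneously when stress-testing assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeTable


@dataclass(frozen=True)
class ErrorSpec:
    ado_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ado_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def inject_ado(table: GenotypeTable, rate: float, seed: int) -> GenotypeTable:
    """With probability ``rate`` per heterozygous call, drop one allele.

    The surviving allele (chosen uniformly) overwrites the other, producing a
    false homozygote.  Homozygous and missing calls are never touched, and no
    allele absent from the original call is ever created.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alleles = table.alleles.copy()
    het = (alleles[:, :, 0] != alleles[:, :, 1]) & (alleles[:, :, 0] != MISSING)
    hit = het & (rng.random(het.shape) < rate)
    keep_second = rng.integers(0, 2, size=het.shape).astype(bool)
    survivor = np.where(keep_second, alleles[:, :, 1], alleles[:, :, 0])
    alleles[:, :, 0] = np.where(hit, survivor, alleles[:, :, 0])
    alleles[:, :, 1] = np.where(hit, survivor, alleles[:, :, 1])
    return GenotypeTable(list(table.individual_ids), list(table.labels),
                         alleles, table.panel)


def inject_missing(table: GenotypeTable, rate: float, seed: int) -> GenotypeTable:
    """Independently per individual x locus, erase the call with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alleles = table.alleles.copy()
    hit = rng.random(alleles.shape[:2]) < rate
    alleles[hit] = MISSING
    return GenotypeTable(list(table.individual_ids), list(table.labels),
                         alleles, table.panel)


def degrade(table: GenotypeTable, spec: ErrorSpec) -> GenotypeTable:
    """Apply ADO then missingness with seeds derived from ``spec.seed``."""
    s_ado, s_miss = (
        int(s) for s in np.random.SeedSequence([spec.seed, 17]).generate_state(2)
        % (2 ** 31)
    )
    out = inject_ado(table, spec.ado_rate, s_ado)
    return inject_missing(out, spec.missing_rate, s_miss)


def assignment_discrepancy(
    q_clean: dict[str, float] | pd.Series,
    q_degraded: dict[str, float] | pd.Series,
) -> float:
    """Mean absolute difference of wild-cluster q across shared individuals.

    Both arguments map individual id -> posterior mean wild-cluster
    membership; the individual sets must match exactly.  Reported on the 0-1
    q scale (a "2% discrepancy" is 0.02).
    """
    qc = pd.Series(q_clean, dtype=float)
    qd = pd.Series(q_degraded, dtype=float)
    if set(qc.index) != set(qd.index):
        raise ValueError("clean and degraded runs cover different individuals")
    if len(qc) == 0:
        raise ValueError("no individuals to compare")
    return float((qc - qd.reindex(qc.index)).abs().mean())
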