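"""Shared fixtures.

All synthetic data are generated at test time from fixed seeds; the heavy
MCMC fixtures are session-scoped so that several tests can interrogate the
same set of posterior assignments.

Problem sizes: the main fixture uses the full 39-locus / 8-allele / FST 0.3
configuration with 100 wild + 95 domestic references and desk-scale chains
(5e3 burn-in + 2e4 sweeps).  The ladder-shape fixture trades reference size
and chain length (60+60 references, 2e3/1e4 chains, 16 individuals per
class) for coverage of all ten admixed classes.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridgate.admixture import (McmcConfig, align_clusters, assign_one_by_one,
                                  run_admixture_mcmc, summarize_individual)
from hybridgate.core_io import concat_tables
from hybridgate.errorsim import ErrorSpec, degrade
from hybridgate.hybsim import build_class_ladder
from hybridgate.synthref import (DivergenceSpec, default_reference_fixture,
                                 draw_parental_frequencies,
                                 sample_reference_population)

FIXTURE_SEED = 11


def take_label(table, label, n=None):
    idx = [i for i, lab in enumerate(table.labels) if lab == label]
    if n is not None:
        idx = idx[:n]
    return table.take(idx)


@pytest.fixture(scope="session")
def freqs_and_refs():
    """Frequencies + 100 RW / 95 RD references (39 loci, 8 alleles, F=0.3)."""
    return default_reference_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def ladder_small(freqs_and_refs):
    """50 individuals per ladder class from the main fixture frequencies."""
    freqs, _ = freqs_and_refs
    return build_class_ladder(freqs, n_per_class=50, seed=FIXTURE_SEED + 1)


@pytest.fixture(scope="session")
def f1_assignments(freqs_and_refs, ladder_small):
    """One-by-one assignment of 50 simulated F1 against the full references."""
    freqs, refs = freqs_and_refs
    f1 = take_label(ladder_small, "F1")
    cfg = McmcConfig(seed=FIXTURE_SEED + 2)
    return assign_one_by_one(refs, f1, cfg)


@pytest.fixture(scope="session")
def reference_run(freqs_and_refs):
    """Single anchored K=2 run over the combined reference panel."""
    freqs, refs = freqs_and_refs
    cfg = McmcConfig(seed=FIXTURE_SEED + 3)
    run = align_clusters(run_admixture_mcmc(refs, cfg))
    return [summarize_individual(run, i) for i in refs.individual_ids]


@pytest.fixture(scope="session")
def degradation_assignments(freqs_and_refs, ladder_small, f1_assignments):
    """Clean vs 30% ADO + 30% missing assignments across the full ladder.

    Five individuals from each of the 12 simulated classes (proportional to
    the standard 100-per-class dataset), assigned one-by-one before and
    after degradation.  Returns (clean, degraded) dicts of individual_id ->
    q_wild_mean.  Per-query seeds derive from the config seed and query
    identity, so the clean and degraded runs of the same individual share a
    chain seed.
    """
    from hybridgate.hybsim import LADDER_CLASSES

    freqs, refs = freqs_and_refs
    n_each = 5
    cfg = McmcConfig(seed=FIXTURE_SEED + 2)

    clean: dict[str, float] = {
        r.individual_id: r.q_wild_mean for r in f1_assignments[:n_each]
    }
    degraded: dict[str, float] = {}
    spec = ErrorSpec(ado_rate=0.30, missing_rate=0.30, seed=FIXTURE_SEED + 4)
    for cls in LADDER_CLASSES:
        tbl = take_label(ladder_small, cls, n_each)
        if cls != "F1":
            for r in assign_one_by_one(refs, tbl, cfg):
                clean[r.individual_id] = r.q_wild_mean
        for r in assign_one_by_one(refs, degrade(tbl, spec), cfg):
            degraded[r.individual_id] = r.q_wild_mean
    return clean, degraded


@pytest.fixture(scope="session")
def ladder_assignments():
    """Reduced-scale ladder assignments covering PW and all admixed classes.

    60+60 references, 16 individuals per class, shortened chains: enough to
    resolve the qualitative q ladder (medians, CI widths, overlap with the
    pure region) at tolerable cost.
    """
    spec = DivergenceSpec(seed=FIXTURE_SEED)
    freqs = draw_parental_frequencies(spec)
    ss = np.random.SeedSequence([FIXTURE_SEED, 9])
    s_w, s_d = (int(s) for s in ss.generate_state(2) % (2 ** 31))
    refs = concat_tables([
        sample_reference_population(freqs, "wild", 60, s_w, label="RW"),
        sample_reference_population(freqs, "domestic", 60, s_d, label="RD"),
    ])
    classes = ("PW", "F1", "F2", "BC1W", "BC2W", "BC3W", "BC4W",
               "BC5W", "BC6W", "BC7W", "BC8W")
    ladder = build_class_ladder(freqs, n_per_class=16, seed=FIXTURE_SEED + 5,
                                classes=classes)
    cfg = McmcConfig(n_burnin=2_000, n_iter=10_000, seed=FIXTURE_SEED + 6)
    return assign_one_by_one(refs, ladder, cfg)
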