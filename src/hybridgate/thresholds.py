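"""Performance analysis over q-thresholds and three-way classification.

The workflow's decision layer: given per-individual wild-cluster membership
coefficients (q_iw) with known simulated ladder classes, it

1. scans a grid of candidate q-thresholds (0.500-0.995 in steps of 0.005,
   plus a terminal 0.999) against a nested family of class splits at
   increasing admixture depth,
2. scores every (threshold, split) cell by performance = efficiency x
   accuracy, where efficiency is the fraction of truly admixed individuals
   flagged (sensitivity) and accuracy the fraction of flagged individuals
   that are truly admixed (positive predictive value),
3. retains the highest threshold whose split achieves performance >= 0.90
   (the recent-admixture threshold t_recent), and
4. sets a second, stricter threshold t_pure at the minimum q_iw observed in
   wild parental individuals, below which nothing can be called pure.

Individuals are then classified into three assignment classes mapped to
management categories:

====================  =======================  =======================
q_iw                  assignment class         management category
====================  =======================  =======================
q_iw >= t_pure        pure                     operational pure
t_recent <= q < pure  older admixed            introgressed
q_iw < t_recent       recent admixed           operational hybrid
====================  =======================  =======================

The reference values derived from the 39-STR wolf/dog system are
t_recent = 0.955 and t_pure = 0.995 (0.975/0.990 for the reduced 12-STR
panel); they are inputs here, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Ladder from the pure-wild end toward increasing admixture, as used by the
#: nested split family (the domestic parental is never part of a split).
SPLIT_LADDER = ("PW", "BC8W", "BC7W", "BC6W", "BC5W", "BC4W",
                "BC3W", "BC2W", "BC1W", "F2", "F1")

PURE = "pure"
OLDER_ADMIXED = "older_admixed"
RECENT_ADMIXED = "recent_admixed"

CATEGORY_OF_CLASS = {
    PURE: "operational_pure",
    OLDER_ADMIXED: "introgressed",
    RECENT_ADMIXED: "operational_hybrid",
}

#: Category order from most to least admixed (rank is monotone in q).
CATEGORY_RANK = {"operational_hybrid": 0, "introgressed": 1, "operational_pure": 2}


@dataclass(frozen=True)
class ClassSplit:
    """One cut of the ladder into a non-admixed side and an admixed side."""

    name: str
    pure_side: tuple[str, ...]
    admixed_side: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.pure_side) & set(self.admixed_side):
            raise ValueError("split sides must be disjoint")
        if not self.admixed_side:
            raise ValueError("admixed side must be non-empty")


@dataclass(frozen=True)
class ThresholdPair:
    """The two selected q-thresholds; t_recent must sit strictly below t_pure."""

    t_recent: float
    t_pure: float

    def __post_init__(self) -> None:
        if not 0.5 < self.t_recent < self.t_pure <= 1.0:
            raise ValueError(
                f"need 0.5 < t_recent < t_pure <= 1, got "
                f"({self.t_recent}, {self.t_pure})"
            )


def default_threshold_grid() -> np.ndarray:
    """0.500, 0.505, ..., 0.995 plus the terminal 0.999 (101 values)."""
    grid = np.round(np.arange(0.500, 0.9951, 0.005), 3)
    return np.append(grid, 0.999)


def enumerate_splits(ladder_classes: tuple[str, ...] = SPLIT_LADDER) -> list[ClassSplit]:
    """Nested splits moving one class at a time onto the pure side.

    Starting from {PW} | {BC8W..F1} and ending with {PW, BC8W..BC2W} |
    {BC1W, F2, F1}; F1, F2 and BC1W never reach the pure side.
    """
    ladder = tuple(ladder_classes)
    if ladder[0] != "PW":
        raise ValueError("the ladder must start at the pure-wild end (PW)")
    splits = []
    last_pure = len(ladder) - 3  # keep BC1W, F2, F1 always admixed
    for cut in range(1, last_pure + 1):
        splits.append(ClassSplit(
            name=f"S{cut}",
            pure_side=ladder[:cut],
            admixed_side=ladder[cut:],
        ))
    return splits


def efficiency_accuracy(
    q_values: pd.DataFrame,
    split: ClassSplit,
    t: float,
    mode: str = "one_sided",
) -> tuple[float, float]:
    """Efficiency and accuracy of calling "admixed" at threshold ``t``.

    ``q_values`` needs columns ``label`` (true simulated class) and
    ``q_wild``; an individual is called admixed iff ``q_wild < t``.  In the
    default one-sided reading, efficiency is the sensitivity for the admixed
    side and accuracy its positive predictive value.  ``mode="two_sided"``
    averages each quantity with its pure-side counterpart.
    """
    labels = q_values["label"].to_numpy()
    q = q_values["q_wild"].to_numpy(dtype=float)
    relevant = np.isin(labels, split.pure_side + split.admixed_side)
    labels, q = labels[relevant], q[relevant]
    is_admixed = np.isin(labels, split.admixed_side)
    called = q < t
    if not is_admixed.any():
        raise ValueError(f"split {split.name}: no true admixed individuals present")
    tp = int((called & is_admixed).sum())
    efficiency = tp / int(is_admixed.sum())
    # vacuous accuracy: nothing called admixed -> no false calls either
    accuracy = tp / int(called.sum()) if called.any() else 1.0
    if mode == "two_sided":
        tn = int((~called & ~is_admixed).sum())
        n_pure = int((~is_admixed).sum())
        eff_pure = tn / n_pure if n_pure else 1.0
        acc_pure = tn / int((~called).sum()) if (~called).any() else 1.0
        efficiency = 0.5 * (efficiency + eff_pure)
        accuracy = 0.5 * (accuracy + acc_pure)
    elif mode != "one_sided":
        raise ValueError("mode must be 'one_sided' or 'two_sided'")
    return float(efficiency), float(accuracy)


def performance_grid(
    q_values: pd.DataFrame,
    splits: list[ClassSplit] | None = None,
    grid: np.ndarray | None = None,
    mode: str = "one_sided",
) -> pd.DataFrame:
    """Long-format grid: one row per (threshold, split) with the three scores."""
    if splits is None:
        present = set(q_values["label"])
        ladder = tuple(c for c in SPLIT_LADDER if c in present)
        splits = enumerate_splits(ladder) if ladder and ladder[0] == "PW" \
            else enumerate_splits()
    if grid is None:
        grid = default_threshold_grid()
    rows = []
    for split in splits:
        for t in grid:
            eff, acc = efficiency_accuracy(q_values, split, float(t), mode=mode)
            rows.append((float(t), split.name, eff, acc, eff * acc))
    return pd.DataFrame(
        rows, columns=["threshold", "split_name", "efficiency", "accuracy",
                       "performance"],
    )


def select_recent_threshold(
    grid: pd.DataFrame, min_performance: float = 0.90
) -> tuple[float, pd.DataFrame]:
    """Most conservative threshold among the well-performing splits.

    A split is retained when its best performance reaches
    ``min_performance``.  Within each retained split the candidate is the
    HIGHEST threshold attaining that split's maximum performance (top of the
    plateau); across retained splits the highest candidate wins, so the
    final t_recent is as conservative (admixture-inclusive) as the data
    allow.  Returns (t_recent, retained-split summary).
    """
    best = (
        grid.groupby("split_name")["performance"].max().rename("best_performance")
    )
    retained = best[best >= min_performance]
    if retained.empty:
        raise ValueError(
            "no split reaches the minimum performance; the marker panel does "
            "not resolve any admixture depth reliably - consider more markers"
        )
    summary = []
    for split_name, best_perf in retained.items():
        sub = grid[grid["split_name"] == split_name]
        plateau = sub[np.isclose(sub["performance"], best_perf)]
        summary.append((split_name, float(best_perf),
                        float(plateau["threshold"].max())))
    summary = pd.DataFrame(
        summary, columns=["split_name", "best_performance", "best_threshold"]
    )
    return float(summary["best_threshold"].max()), summary


def select_pure_threshold(
    q_values: pd.DataFrame,
    wild_parental_labels: tuple[str, ...] = ("RW", "PW"),
) -> float:
    """Minimum wild-parental q_iw, floored to 3 decimals.

    Flooring guarantees the defining parental individual still satisfies
    ``q >= t_pure``.
    """
    mask = q_values["label"].isin(wild_parental_labels)
    if not mask.any():
        raise ValueError("no wild parental individuals in the q table")
    t = float(q_values.loc[mask, "q_wild"].min())
    return float(np.floor(t * 1000.0) / 1000.0)


def classify_individual(q_wild: float, thresholds: ThresholdPair) -> tuple[str, str]:
    """(assignment class, management category) for one q_iw value."""
    if q_wild >= thresholds.t_pure:
        cls = PURE
    elif q_wild >= thresholds.t_recent:
        cls = OLDER_ADMIXED
    else:
        cls = RECENT_ADMIXED
    return cls, CATEGORY_OF_CLASS[cls]


def classify_table(q_values: pd.DataFrame, thresholds: ThresholdPair) -> pd.DataFrame:
    """Vectorised classification; adds assignment_class / management_category."""
    out = q_values.copy()
    q = out["q_wild"].to_numpy(dtype=float)
    cls = np.where(q >= thresholds.t_pure, PURE,
                   np.where(q >= thresholds.t_recent, OLDER_ADMIXED,
                            RECENT_ADMIXED))
    out["assignment_class"] = cls
    out["management_category"] = [CATEGORY_OF_CLASS[c] for c in cls]
    return out


def error_rates(
    classified: pd.DataFrame,
    pure_labels: tuple[str, ...] = ("PW", "RW"),
    admixed_labels: tuple[str, ...] = ("F1", "F2", "BC1W", "BC2W", "BC3W",
                                       "BC4W", "BC5W", "BC6W", "BC7W", "BC8W"),
) -> tuple[float, float, pd.DataFrame]:
    """Type-I / type-II error rates plus a per-class confusion table.

    Type I: truly pure individuals not classified pure.  Type II: truly
    admixed individuals classified pure.  The confusion table gives, per
    true ladder class, the percentage falling in each management category.
    """
    lab = classified["label"]
    cls = classified["assignment_class"]
    pure_mask = lab.isin(pure_labels)
    adm_mask = lab.isin(admixed_labels)
    type_i = float((cls[pure_mask] != PURE).mean()) if pure_mask.any() else 0.0
    type_ii = float((cls[adm_mask] == PURE).mean()) if adm_mask.any() else 0.0
    conf = (
        classified.groupby("label")["management_category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .mul(100.0)
    )
    for cat in CATEGORY_OF_CLASS.values():
        if cat not in conf.columns:
            conf[cat] = 0.0
    conf = conf[list(CATEGORY_OF_CLASS.values())]
    return type_i, type_ii, conf
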