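"""Downstream scoring of immunoaffinity-purification mass spectrometry data.

Implements the label-free and isotope-labeled analysis of bait (huntingtin)
co-isolated proteins: SAINT specificity aggregation (mean of the two
highest per-group scores, specific at >= 0.8), bait-level normalization of
label-free abundances, the quantified-protein filter, minimum-CV replicate
selection, differential interaction calls (Student's t on log2 abundances,
|log2 FC| and p-value thresholds), light/(light+heavy) isotope stability
ratios, specific-and-stable quadrant assignment, and Venn partitioning of
interactor sets across tissues and polyQ lengths.

Abundance matrices are pandas DataFrames with proteins as rows and samples
as columns named ``<group>_<replicate>`` (e.g. ``Q140-2M_r1``); missing
quantifications are NaN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    BaitQuantError,
    EmptyInputError,
    InvalidThresholdError,
)

#: The four sample groups of the cortex study design.
DEFAULT_GROUPS = ("Q20-2M", "Q140-2M", "Q20-10M", "Q140-10M")


@dataclass(frozen=True)
class SpecStableCall:
    """Quadrant assignment of one interactor in one sample group."""

    gene: str
    group: str
    saint_avg: float
    stability: Optional[float]
    classification: str  # specific_stable | specific_only | stable_only | neither
    stability_missing: bool = False


def group_columns(matrix: pd.DataFrame, group: str) -> list[str]:
    """Columns of ``matrix`` belonging to one sample group."""
    prefix = f"{group}_"
    return [c for c in matrix.columns if c.startswith(prefix)]


def saint_specificity(
    scores: Sequence[float],
    threshold: float = 0.8,
) -> tuple[float, bool]:
    """Average the two highest SAINT scores; specific at >= threshold.

    SAINT emits a probability-like specificity score in [0, 1] per IP
    sample; per group the two best are averaged and the interaction is
    called specific when that average reaches the threshold (inclusive).
    """
    scores = list(scores)
    if len(scores) < 2:
        raise EmptyInputError("saint_specificity requires at least 2 scores")
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise InvalidThresholdError("saint score", s, "[0, 1]")
    top2 = sorted(scores, reverse=True)[:2]
    avg = float(np.mean(top2))
    return avg, avg >= threshold


def normalize_to_bait(
    matrix: pd.DataFrame,
    bait_gene: str,
) -> pd.DataFrame:
    """Normalize each sample's abundances to the bait protein level.

    Every protein's abundance in sample ``s`` is divided by the bait's
    abundance in ``s`` and rescaled by the across-sample mean bait
    abundance, so the bait becomes constant across samples and abundance
    units are preserved.
    """
    if bait_gene not in matrix.index:
        raise BaitQuantError(bait_gene, "<absent from matrix>")
    bait = matrix.loc[bait_gene]
    for sample, value in bait.items():
        if pd.isna(value) or value <= 0:
            raise BaitQuantError(bait_gene, str(sample))
    return matrix.div(bait, axis=1) * float(bait.mean())


def filter_quantified(
    matrix: pd.DataFrame,
    groups: Sequence[str] = DEFAULT_GROUPS,
    min_values: int = 2,
) -> pd.DataFrame:
    """Keep proteins with >= ``min_values`` quantified replicates in at
    least one sample group."""
    keep = []
    for protein in matrix.index:
        row = matrix.loc[protein]
        for group in groups:
            cols = group_columns(matrix, group)
            if cols and int(row[cols].notna().sum()) >= min_values:
                keep.append(protein)
                break
    return matrix.loc[keep]


def select_replicates_min_cv(
    matrix: pd.DataFrame,
    group: str,
    keep: int = 2,
) -> list[str]:
    """Choose the ``keep`` replicates of a group minimizing replicate CV.

    Every size-``keep`` column subset is evaluated; per subset the
    coefficient of variation (sd/mean, ddof=1) is computed for each
    protein fully quantified in the subset, and subsets are ranked by the
    median CV across those proteins. Ties break by lexicographic column
    order.
    """
    cols = group_columns(matrix, group)
    if len(cols) < keep:
        raise InvalidThresholdError("keep", keep, f"<= {len(cols)} replicates")
    best: tuple | None = None
    for subset in itertools.combinations(sorted(cols), keep):
        sub = matrix[list(subset)].dropna()
        sub = sub[(sub > 0).all(axis=1)] if not sub.empty else sub
        if sub.empty:
            continue
        means = sub.mean(axis=1)
        sds = sub.std(axis=1, ddof=1)
        cv = float((sds / means).median())
        key = (cv, subset)
        if best is None or key < best:
            best = key
    if best is None:
        raise EmptyInputError(
            f"no protein fully quantified in any replicate subset of {group}"
        )
    return list(best[1])


def differential_interactions(
    matrix: pd.DataFrame,
    group_a: str,
    group_b: str,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential interaction abundance between two sample groups.

    For each protein with >= 2 quantified replicates in both groups:
    log2fc = log2(mean_b / mean_a) on (bait-normalized) abundances; the
    p-value is a two-sided equal-variance Student's t-test on log2
    abundances; ``call`` is |log2fc| >= fc_threshold and p < alpha.
    Proteins failing the replicate requirement are returned with
    ``tested = False``. A degenerate comparison (zero variance in both
    groups, equal means) yields p = 1 and no call.
    """
    cols_a = group_columns(matrix, group_a)
    cols_b = group_columns(matrix, group_b)
    rows = []
    for protein in matrix.index:
        a = matrix.loc[protein, cols_a].dropna().astype(float)
        b = matrix.loc[protein, cols_b].dropna().astype(float)
        a = a[a > 0]
        b = b[b > 0]
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {"protein": protein, "log2fc": np.nan, "p_value": np.nan,
                 "call": False, "tested": False}
            )
            continue
        log2fc = float(np.log2(b.mean() / a.mean()))
        la, lb = np.log2(a.values), np.log2(b.values)
        if np.ptp(la) == 0 and np.ptp(lb) == 0:
            p = 0.0 if la[0] != lb[0] else 1.0
        else:
            p = float(stats.ttest_ind(lb, la, equal_var=True).pvalue)
        call = (abs(log2fc) >= fc_threshold) and (p < alpha)
        rows.append(
            {"protein": protein, "log2fc": log2fc, "p_value": p,
             "call": call, "tested": True}
        )
    return pd.DataFrame(rows).set_index("protein")


def stability_ratio(light: float, heavy: float) -> float:
    """Isotope interaction stability ratio light / (light + heavy).

    An endogenous (light) bait complex is mixed with a heavy-labeled
    reference lysate before purification; a ratio near 1 means little
    in-solution exchange (a stable interaction), near 0.5 a
    fast-exchanging or transient association.
    """
    if light < 0 or heavy < 0:
        raise InvalidThresholdError("intensity", (light, heavy), ">= 0")
    if light + heavy == 0:
        raise EmptyInputError("light and heavy intensities are both zero")
    return light / (light + heavy)


def assign_specific_stable(
    gene: str,
    group: str,
    saint_avg: float,
    stability: Optional[float],
    saint_threshold: float = 0.8,
    stability_threshold: float = 0.75,
) -> SpecStableCall:
    """Quadrant classification of specificity vs stability.

    ``specific_stable`` requires saint_avg >= saint_threshold and
    stability >= stability_threshold (the upper-right quadrant of the
    specificity/stability plane); the other classes follow. A missing
    stability ratio is classified on specificity alone and flagged.
    """
    if not 0.0 <= saint_threshold <= 1.0:
        raise InvalidThresholdError("saint_threshold", saint_threshold, "[0, 1]")
    if not 0.5 < stability_threshold < 1.0:
        raise InvalidThresholdError(
            "stability_threshold", stability_threshold, "(0.5, 1.0)"
        )
    specific = saint_avg >= saint_threshold
    if stability is None:
        cls = "specific_only" if specific else "neither"
        return SpecStableCall(gene, group, saint_avg, None, cls,
                              stability_missing=True)
    stable = stability >= stability_threshold
    if specific and stable:
        cls = "specific_stable"
    elif specific:
        cls = "specific_only"
    elif stable:
        cls = "stable_only"
    else:
        cls = "neither"
    return SpecStableCall(gene, group, saint_avg, stability, cls)


def venn_partition(named_sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exhaustive membership-region counts for 2-4 named sets.

    Returns a count for every non-empty label subset; counts sum to the
    size of the union.
    """
    labels = list(named_sets)
    if not 2 <= len(labels) <= 4:
        raise InvalidThresholdError("number of sets", len(labels), "2-4")
    universe = set().union(*named_sets.values())
    counts: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            counts[frozenset(combo)] = 0
    for item in universe:
        membership = frozenset(
            lab for lab in labels if item in named_sets[lab]
        )
        counts[membership] += 1
    return counts
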