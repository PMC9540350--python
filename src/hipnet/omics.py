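"""Per-gene and network-aggregated omics views.

Bulk RNA/protein values are log2 ratios of a disease-length polyQ knock-in
versus the Q20 control, indexed by (tissue, age in months, Q length);
single-nucleus values are log2(Q175/WT) per striatal cell type; single-cell
values are the fraction of cells expressing the gene. Aggregation over a
filtered network uses the median for log2-ratio modalities (a sum of log
ratios has no central-tendency reading) and the sum for expression
fractions; both are overridable.

The 90% bounding envelope marks, per (tissue, age, Q) stratum, the 5th and
95th percentiles of the values across all genes — a point outside the
envelope sits in the upper or lower 5% of the data at that Q length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .catalog import MODALITIES, OmicsMeasurement
from .errors import EmptyInputError, InvalidThresholdError

#: Default aggregation statistic per modality.
AGGREGATORS = {
    "bulk_rna": "median",
    "bulk_protein": "median",
    "snrna_fc": "median",
    "scrna_fraction": "sum",
}


@dataclass
class OmicsSeries:
    """Indexed omics values for one gene or one aggregate label.

    The index is (tissue, age_months, q_length) for bulk modalities and
    (cell_type,) for single-cell modalities; index tuples are unique.
    """

    label: str
    modality: str
    values: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def items(self):
        return sorted(self.values.items(), key=lambda kv: tuple(map(str, kv[0])))


def _index_of(m: OmicsMeasurement) -> tuple:
    if m.modality in ("snrna_fc", "scrna_fraction"):
        return (m.cell_type,)
    return (m.tissue, m.age_months, m.q_length)


def node_omics(
    measurements: Iterable[OmicsMeasurement],
    gene: str,
    modality: str,
) -> OmicsSeries:
    """All measurements for one gene in one modality (possibly empty)."""
    if modality not in MODALITIES:
        raise InvalidThresholdError("modality", modality, f"one of {MODALITIES}")
    series = OmicsSeries(label=gene, modality=modality)
    for m in measurements:
        if m.gene_symbol_human == gene and m.modality == modality:
            series.values[_index_of(m)] = m.value
    return series


def aggregate_omics(
    measurements: Iterable[OmicsMeasurement],
    genes: set[str],
    modality: str,
    statistic: str | None = None,
) -> OmicsSeries:
    """Aggregate one modality across a gene set, per index tuple.

    ``statistic`` defaults per modality (median for log2 ratios, sum for
    fractions) and may be overridden with "median" or "sum". Genes missing
    a tuple are simply absent from that tuple's aggregate.
    """
    if modality not in MODALITIES:
        raise InvalidThresholdError("modality", modality, f"one of {MODALITIES}")
    if not genes:
        raise EmptyInputError("aggregate_omics requires a non-empty gene set")
    stat = statistic or AGGREGATORS[modality]
    if stat not in ("median", "sum"):
        raise InvalidThresholdError("statistic", stat, "median or sum")
    per_tuple: dict[tuple, list[float]] = {}
    for m in measurements:
        if m.modality == modality and m.gene_symbol_human in genes:
            per_tuple.setdefault(_index_of(m), []).append(m.value)
    agg = np.median if stat == "median" else np.sum
    series = OmicsSeries(label=f"aggregate[{stat}]", modality=modality)
    for idx, vals in per_tuple.items():
        series.values[idx] = float(agg(vals))
    return series


def bounding_envelope(values: Sequence[float]) -> tuple[float, float]:
    """(5th, 95th) percentile bounds containing 90% of the data.

    Percentiles use linear interpolation between closest order statistics.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyInputError("bounding_envelope requires at least one value")
    lo, hi = np.percentile(arr, [5.0, 95.0], method="linear")
    return float(lo), float(hi)


def envelope_by_stratum(
    measurements: Iterable[OmicsMeasurement],
    modality: str,
) -> dict[tuple, tuple[float, float]]:
    """Bounding envelope per (tissue, age, Q) stratum across all genes."""
    per_stratum: dict[tuple, list[float]] = {}
    for m in measurements:
        if m.modality == modality:
            per_stratum.setdefault(_index_of(m), []).append(m.value)
    return {idx: bounding_envelope(vals) for idx, vals in per_stratum.items()}


def highlight_snrna(
    series: OmicsSeries,
    threshold: float = 0.15,
) -> dict[str, str]:
    """Classify cell types by single-nucleus fold change.

    ``up`` when log2(Q175/WT) >= threshold (inclusive), ``down`` when
    <= -threshold, else ``none``. The default 0.15 corresponds to a
    >10% change in either direction (2**0.15 - 1 ≈ 11%).
    """
    if series.modality != "snrna_fc":
        raise InvalidThresholdError("modality", series.modality, "snrna_fc")
    out = {}
    for (cell_type,), value in series.values.items():
        if value >= threshold:
            out[cell_type] = "up"
        elif value <= -threshold:
            out[cell_type] = "down"
        else:
            out[cell_type] = "none"
    return out


def highlight_scrna(
    series: OmicsSeries,
    threshold: float = 0.8,
) -> dict[str, bool]:
    """Flag cell types where the expressing-cell fraction is >= threshold."""
    if series.modality != "scrna_fraction":
        raise InvalidThresholdError("modality", series.modality, "scrna_fraction")
    out = {}
    for (cell_type,), value in series.values.items():
        if not 0.0 <= value <= 1.0:
            raise InvalidThresholdError("scrna_fraction", value, "[0, 1]")
        out[cell_type] = value >= threshold
    return out
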