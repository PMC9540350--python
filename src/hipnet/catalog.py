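"""Unified huntingtin interactor + omics catalog.

The catalog merges per-observation protein interaction reports (each row one
experimental detection of a candidate huntingtin-interacting protein, with its
model organism, tissue, construct length, detection method and study of
origin) with multi-omics measurements from knock-in mouse allelic-series
models. Non-human gene symbols are mapped to human orthologs via static
lookup tables; records without a human ortholog are excluded. The resulting
human-gene-centric catalog flags each gene as a HIP (huntingtin-interacting
protein) when at least one study reports a confirmed interaction, and counts
the distinct supporting studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import MissingColumnError

#: Metadata columns available for interaction-level filtering.
METADATA_FIELDS = (
    "model_species",
    "tissue",
    "htt_length",
    "detection_method",
    "common_name",
    "cell_culture_comment",
    "study_id",
)

#: Tuple of fields defining observation uniqueness during merging.
DEDUP_KEY = (
    "gene_symbol_source",
    "study_id",
    "model_species",
    "tissue",
    "htt_length",
    "detection_method",
)

MODALITIES = ("bulk_rna", "bulk_protein", "snrna_fc", "scrna_fraction")


@dataclass(frozen=True)
class PPIObservation:
    """One reported interaction detection with its experimental metadata."""

    obs_id: str
    gene_symbol_human: str
    gene_symbol_source: str
    study_id: str
    model_species: str = ""
    tissue: str = ""
    htt_length: str = ""
    detection_method: str = ""
    common_name: str = ""
    cell_culture_comment: str = ""
    interaction_confirmed: bool = False
    entrez_id: Optional[int] = None

    def metadata(self, field_name: str) -> str:
        if field_name not in METADATA_FIELDS:
            raise KeyError(field_name)
        return getattr(self, field_name)


@dataclass
class GeneRecord:
    """Human-ortholog-centric catalog entry.

    ``is_hip`` is true iff the gene has at least one confirmed interaction
    observation; ``study_count`` is the number of distinct studies with a
    confirmed observation. Annotations map a label to either a set of
    category strings (multi-valued labels such as subcellular localization
    are preserved as sets) or a numeric value.
    """

    gene_symbol_human: str
    entrez_id: Optional[int] = None
    is_hip: bool = False
    study_count: int = 0
    annotations: dict = field(default_factory=dict)


@dataclass(frozen=True)
class OmicsMeasurement:
    """One omics value for a gene.

    Bulk modalities (``bulk_rna``, ``bulk_protein``) carry tissue, age and
    polyQ length and hold sex-averaged log2 ratios vs the Q20 control.
    Single-cell modalities carry a cell type; ``snrna_fc`` holds
    log2(Q175/WT) and ``scrna_fraction`` the fraction of cells expressing
    the gene (in [0, 1]).
    """

    gene_symbol_human: str
    modality: str
    value: float
    tissue: Optional[str] = None
    age_months: Optional[int] = None
    q_length: Optional[int] = None
    cell_type: Optional[str] = None

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "scrna_fraction" and not (0.0 <= self.value <= 1.0):
            raise ValueError(
                f"scrna_fraction value {self.value} outside [0, 1]"
            )


class OrthologMap:
    """Static (organism, source symbol) -> (human symbol, entrez id) table.

    Lookups are deterministic; a missing entry signals exclusion of the
    source record, never a fallback.
    """

    def __init__(self, entries: Mapping[tuple, tuple] | None = None):
        self._entries = {
            (org.strip().casefold(), sym.strip().casefold()): (hsym, eid)
            for (org, sym), (hsym, eid) in (entries or {}).items()
        }

    def lookup(self, organism: str, symbol: str):
        return self._entries.get(
            (organism.strip().casefold(), symbol.strip().casefold())
        )

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "OrthologMap":
        """Build from a table with columns source_organism, source_symbol,
        human_symbol, entrez_id."""
        for col in ("source_organism", "source_symbol", "human_symbol"):
            if col not in df.columns:
                raise MissingColumnError(col, "ortholog map")
        entries = {}
        for row in df.itertuples(index=False):
            eid = getattr(row, "entrez_id", None)
            eid = int(eid) if eid is not None and not pd.isna(eid) else None
            entries[(row.source_organism, row.source_symbol)] = (
                row.human_symbol,
                eid,
            )
        return cls(entries)


def combine_model_columns(model: str, model_organism: str) -> str:
    """Collapse the partially redundant model / model-organism columns.

    The organism string wins when both are present and unequal; otherwise
    the non-empty one passes through. Both empty yields ``"unspecified"``.
    """
    model = (model or "").strip()
    organism = (model_organism or "").strip()
    if organism:
        return organism
    if model:
        return model
    return "unspecified"


_RAW_COLUMNS = {
    "gene_symbol_source": "gene_symbol",
    "study_id": "study_identifier",
    "interaction_result": "interaction_result",
}


def merge_ppi_catalog(
    base_table: pd.DataFrame,
    supplements: Sequence[pd.DataFrame] = (),
    column_map: Mapping[str, str] | None = None,
) -> list[PPIObservation]:
    """Concatenate a base interaction table with supplemental studies.

    Rows are deduplicated on the full metadata tuple
    (source symbol, study, model species, tissue, construct length,
    detection method); the first occurrence in input order wins and
    observation ids are assigned deterministically by input order.

    Raw tables carry `model` and `model_organism` columns which are merged
    into `model_species`; `interaction_result` of "Y" (after whitespace
    trim) marks a confirmed interaction.
    """
    colmap = dict(_RAW_COLUMNS)
    if column_map:
        colmap.update(column_map)

    tables = [base_table, *supplements]
    observations: list[PPIObservation] = []
    seen: set[tuple] = set()
    counter = 0
    for table in tables:
        for mandatory in ("gene_symbol_source", "study_id", "interaction_result"):
            if colmap[mandatory] not in table.columns:
                raise MissingColumnError(colmap[mandatory], "PPI table")
        df = table.fillna("")
        for row in df.to_dict("records"):
            model_species = combine_model_columns(
                str(row.get("model", "")), str(row.get("model_organism", ""))
            )
            rec = {
                "gene_symbol_source": str(row[colmap["gene_symbol_source"]]).strip(),
                "study_id": str(row[colmap["study_id"]]).strip(),
                "model_species": model_species,
                "tissue": str(row.get("tissue", "")).strip(),
                "htt_length": str(row.get("htt_length", "")).strip(),
                "detection_method": str(row.get("detection_method", "")).strip(),
            }
            key = tuple(rec[k] for k in DEDUP_KEY)
            if key in seen:
                continue
            seen.add(key)
            obs = PPIObservation(
                obs_id=f"obs{counter:06d}",
                gene_symbol_human="",  # assigned by map_orthologs
                gene_symbol_source=rec["gene_symbol_source"],
                study_id=rec["study_id"],
                model_species=rec["model_species"],
                tissue=rec["tissue"],
                htt_length=rec["htt_length"],
                detection_method=rec["detection_method"],
                common_name=str(row.get("common_name", "")).strip(),
                cell_culture_comment=str(row.get("cell_culture_comment", "")).strip(),
                interaction_confirmed=(
                    str(row[colmap["interaction_result"]]).strip() == "Y"
                ),
            )
            counter += 1
            observations.append(obs)
    return observations


_HUMAN_TOKENS = {"human", "homo sapiens", "h. sapiens"}


def map_orthologs(
    observations: Iterable[PPIObservation],
    ortholog_map: OrthologMap,
) -> tuple[list[PPIObservation], int]:
    """Replace source symbols by human ortholog symbols.

    Human records pass through with their symbol upper-cased per human
    nomenclature. Non-human records with no map entry are dropped; the
    second return value counts them.
    """
    mapped: list[PPIObservation] = []
    excluded = 0
    for obs in observations:
        species = obs.model_species.strip().casefold()
        if species in _HUMAN_TOKENS:
            mapped.append(
                _with_human(obs, obs.gene_symbol_source.upper(), obs.entrez_id)
            )
            continue
        hit = ortholog_map.lookup(obs.model_species, obs.gene_symbol_source)
        if hit is None:
            excluded += 1
            continue
        human_symbol, entrez = hit
        mapped.append(_with_human(obs, human_symbol, entrez))
    return mapped, excluded


def _with_human(obs: PPIObservation, symbol: str, entrez) -> PPIObservation:
    return PPIObservation(
        obs_id=obs.obs_id,
        gene_symbol_human=symbol,
        gene_symbol_source=obs.gene_symbol_source,
        study_id=obs.study_id,
        model_species=obs.model_species,
        tissue=obs.tissue,
        htt_length=obs.htt_length,
        detection_method=obs.detection_method,
        common_name=obs.common_name,
        cell_culture_comment=obs.cell_culture_comment,
        interaction_confirmed=obs.interaction_confirmed,
        entrez_id=entrez,
    )


def filter_confirmed(
    observations: Iterable[PPIObservation],
) -> list[PPIObservation]:
    """Keep only observations flagged as confirmed interactions."""
    return [o for o in observations if o.interaction_confirmed]


def build_catalog(
    omics_measurements: Iterable[OmicsMeasurement],
    confirmed_observations: Iterable[PPIObservation],
) -> dict[str, GeneRecord]:
    """Build the human-gene-centric catalog.

    One record per distinct human gene appearing in either input. Genes
    with omics data but no interaction report get ``is_hip=False``;
    ``study_count`` counts distinct studies with a confirmed observation.
    """
    catalog: dict[str, GeneRecord] = {}
    for m in omics_measurements:
        catalog.setdefault(
            m.gene_symbol_human, GeneRecord(gene_symbol_human=m.gene_symbol_human)
        )
    studies: dict[str, set] = {}
    for obs in confirmed_observations:
        if not obs.interaction_confirmed:
            continue
        rec = catalog.setdefault(
            obs.gene_symbol_human,
            GeneRecord(gene_symbol_human=obs.gene_symbol_human),
        )
        if rec.entrez_id is None and obs.entrez_id is not None:
            rec.entrez_id = obs.entrez_id
        studies.setdefault(obs.gene_symbol_human, set()).add(obs.study_id)
    for gene, sids in studies.items():
        catalog[gene].study_count = len(sids)
        catalog[gene].is_hip = len(sids) >= 1
    return catalog


def average_sexes(bulk_table: pd.DataFrame) -> list[OmicsMeasurement]:
    """Average male/female replicate values of a raw bulk omics table.

    Expects columns gene_symbol_human, modality, tissue, age_months,
    q_length, sex, value; returns one measurement per
    (gene, modality, tissue, age, Q), the arithmetic mean over the sexes
    present. Single-sex rows pass through unchanged.
    """
    for col in ("gene_symbol_human", "modality", "tissue", "age_months",
                "q_length", "value"):
        if col not in bulk_table.columns:
            raise MissingColumnError(col, "bulk omics table")
    keys = ["gene_symbol_human", "modality", "tissue", "age_months", "q_length"]
    grouped = bulk_table.groupby(keys, sort=False)["value"].mean().reset_index()
    return [
        OmicsMeasurement(
            gene_symbol_human=row.gene_symbol_human,
            modality=row.modality,
            tissue=row.tissue,
            age_months=int(row.age_months),
            q_length=int(row.q_length),
            value=float(row.value),
        )
        for row in grouped.itertuples(index=False)
    ]


def write_catalog(catalog: Mapping[str, GeneRecord], path) -> None:
    """Serialize the catalog as TSV, one gene per row.

    Annotations are flattened as ``label=value1,value2`` joined by ``;``.
    """
    rows = []
    for gene in sorted(catalog):
        rec = catalog[gene]
        flat = ";".join(
            f"{label}={_flatten_annotation(v)}"
            for label, v in sorted(rec.annotations.items())
        )
        rows.append(
            {
                "gene_symbol_human": rec.gene_symbol_human,
                "entrez_id": "" if rec.entrez_id is None else rec.entrez_id,
                "is_hip": rec.is_hip,
                "study_count": rec.study_count,
                "annotations": flat,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene_symbol_human", "entrez_id", "is_hip", "study_count",
            "annotations",
        ],
    ).to_csv(path, sep="\t", index=False)


def _flatten_annotation(value) -> str:
    if isinstance(value, (set, frozenset, list, tuple)):
        return ",".join(sorted(str(v) for v in value))
    return str(value)
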