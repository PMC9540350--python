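"""User dataset ingestion and catalog integration.

A user study is a TSV with a gene-symbol column and optional annotation
columns whose headers start with ``QUANT_``. A ``QUANT_x`` column becomes
annotation label ``x``; it is quantitative when every non-missing value
parses as a finite number, otherwise categorical, with categorical values
split on commas into sets (so a protein annotated to several subcellular
compartments keeps all of them). Registered studies become confirmed
interaction observations and the overlap with the prior catalog is
reported as known vs previously unreported genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .catalog import GeneRecord, PPIObservation
from .errors import DuplicateStudyError, MissingColumnError

GENE_COLUMN_ALIASES = ("gene_symbol", "gene", "gene_symbol_human", "symbol")
MISSING_TOKENS = {"", "na", "nan"}
QUANT_PREFIX = "QUANT_"


@dataclass
class UserDataset:
    study_id: str
    records: list  # (gene_symbol_human, annotations dict)
    quant_columns: dict = field(default_factory=dict)  # label -> kind
    dropped_rows: int = 0

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.records}


def _is_missing(value: str) -> bool:
    return value.strip().casefold() in MISSING_TOKENS


def _parses_numeric(value: str) -> bool:
    try:
        return math.isfinite(float(value))
    except ValueError:
        return False


def parse_user_table(
    path,
    study_id: str,
    gene_column_aliases: tuple = GENE_COLUMN_ALIASES,
) -> UserDataset:
    """Parse a user TSV into a dataset of (gene, annotations) records.

    Rows with an empty gene symbol are dropped and counted. Column kinds
    are decided per column: quantitative iff all non-missing values are
    finite numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str,
                     skip_blank_lines=False).fillna("")
    gene_col = next(
        (c for c in df.columns if c.strip().casefold() in
         {a.casefold() for a in gene_column_aliases}),
        None,
    )
    if gene_col is None:
        raise MissingColumnError("gene_symbol", f"user table {path}")

    quant_cols = [c for c in df.columns if c.startswith(QUANT_PREFIX)]
    kinds: dict[str, str] = {}
    for col in quant_cols:
        non_missing = [v for v in df[col] if not _is_missing(v)]
        all_numeric = bool(non_missing) and all(
            _parses_numeric(v) for v in non_missing
        )
        kinds[col[len(QUANT_PREFIX):]] = (
            "quantitative" if all_numeric else "categorical"
        )

    records = []
    dropped = 0
    for row in df.to_dict("records"):
        gene = str(row[gene_col]).strip()
        if not gene:
            dropped += 1
            continue
        annotations = {}
        for col in quant_cols:
            label = col[len(QUANT_PREFIX):]
            raw = str(row[col])
            if _is_missing(raw):
                continue
            if kinds[label] == "quantitative":
                annotations[label] = float(raw)
            else:
                annotations[label] = {
                    v.strip() for v in raw.split(",") if v.strip()
                }
        records.append((gene.upper(), annotations))
    return UserDataset(
        study_id=study_id, records=records, quant_columns=kinds,
        dropped_rows=dropped,
    )


def integrate_study(
    catalog: dict[str, GeneRecord],
    observations: list[PPIObservation],
    dataset: UserDataset,
) -> tuple[list[PPIObservation], dict]:
    """Register a user study: add confirmed observations and report overlap.

    The overlap report partitions the dataset's genes into ``known``
    (at least one prior confirmed observation) and ``novel``. Catalog
    study counts and annotations are updated in place; the returned
    observation list extends the input with the new study's records.

    Raises :class:`DuplicateStudyError` if the study id is already
    present among the observations.
    """
    existing_studies = {o.study_id for o in observations}
    if dataset.study_id in existing_studies:
        raise DuplicateStudyError(dataset.study_id)

    prior_hips = {
        o.gene_symbol_human for o in observations if o.interaction_confirmed
    }
    known = sorted(dataset.genes & prior_hips)
    novel = sorted(dataset.genes - prior_hips)

    new_obs = list(observations)
    for i, (gene, annotations) in enumerate(dataset.records):
        new_obs.append(
            PPIObservation(
                obs_id=f"{dataset.study_id}:{i:05d}",
                gene_symbol_human=gene,
                gene_symbol_source=gene,
                study_id=dataset.study_id,
                interaction_confirmed=True,
            )
        )
        rec = catalog.setdefault(gene, GeneRecord(gene_symbol_human=gene))
        rec.annotations.update(annotations)

    # recompute per-gene distinct-study counts over confirmed observations
    studies: dict[str, set] = {}
    for o in new_obs:
        if o.interaction_confirmed:
            studies.setdefault(o.gene_symbol_human, set()).add(o.study_id)
    for gene, sids in studies.items():
        rec = catalog.setdefault(gene, GeneRecord(gene_symbol_human=gene))
        rec.study_count = len(sids)
        rec.is_hip = True

    report = {
        "study_id": dataset.study_id,
        "known": known,
        "novel": novel,
        "n_known": len(known),
        "n_novel": len(novel),
    }
    return new_obs, report
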