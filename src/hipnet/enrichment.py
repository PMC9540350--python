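"""Local overrepresentation analysis over GMT annotation sets.

Replaces a live pathway-database query with the same statistic computed
offline: a one-sided (greater) Fisher exact test of the query gene set
against each annotation term, relative to a background list, with
Benjamini-Hochberg control of the false discovery rate across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInputError, FileFormatError


@dataclass(frozen=True)
class AnnotationSet:
    """One gene-set term (e.g. a GO or pathway annotation)."""

    term_id: str
    term_name: str
    member_genes: frozenset

    def __post_init__(self):
        if not self.member_genes:
            raise ValueError(f"annotation set {self.term_id} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes in term
    n: int  # query size (restricted to background)
    K: int  # background genes in term
    N: int  # background size
    fold_enrichment: float
    p_value: float
    fdr_q: float


def overrepresentation(
    query_genes: Iterable[str],
    background_genes: Iterable[str],
    annotation_sets: Sequence[AnnotationSet],
) -> tuple[list[EnrichmentResult], int]:
    """Fisher-exact overrepresentation of the query against each term.

    Query genes outside the background are dropped and counted (second
    return value). For each term the one-sided p-value is the
    hypergeometric upper tail P(X >= k) with k overlap, n query genes,
    K background term members, N background genes; q-values are
    Benjamini-Hochberg across all tested terms, results sorted by
    ascending p (ties by term id).
    """
    background = {g.strip().upper() for g in background_genes}
    if len(background) < 2:
        raise EmptyInputError("background must contain at least 2 genes")
    raw_query = {g.strip().upper() for g in query_genes}
    query = raw_query & background
    dropped = len(raw_query - background)
    if not query:
        raise EmptyInputError("no query genes remain inside the background")

    N, n = len(background), len(query)
    rows = []
    for term in annotation_sets:
        members = {g.strip().upper() for g in term.member_genes} & background
        K = len(members)
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        p = min(max(p, 5e-324), 1.0)  # clamp underflow into (0, 1]
        fold = (k / n) / (K / N) if K > 0 and n > 0 else float("nan")
        rows.append((term, k, K, p, fold))

    rows.sort(key=lambda r: (r[3], r[0].term_id))
    if rows:
        _, qvals, _, _ = multipletests(
            [r[3] for r in rows], method="fdr_bh"
        )
    else:
        qvals = []
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            term_name=term.term_name,
            k=k, n=n, K=K, N=N,
            fold_enrichment=fold,
            p_value=p,
            fdr_q=float(q),
        )
        for (term, k, K, p, fold), q in zip(rows, qvals)
    ]
    return results, dropped


def read_gmt(path) -> tuple[list[AnnotationSet], int]:
    """Read annotation sets from a GMT file.

    Each line: term id, description, then member genes, tab-separated.
    Lines with fewer than three fields are skipped and counted (second
    return value); duplicate member symbols deduplicate silently.
    """
    sets: list[AnnotationSet] = []
    skipped = 0
    try:
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                genes = frozenset(g.strip() for g in parts[2:] if g.strip())
                if len(parts) < 3 or not genes:
                    skipped += 1
                    continue
                sets.append(
                    AnnotationSet(
                        term_id=parts[0], term_name=parts[1], member_genes=genes
                    )
                )
    except OSError as exc:
        raise FileFormatError(f"cannot read GMT file {path}: {exc}")
    return sets, skipped


def write_gmt(annotation_sets: Sequence[AnnotationSet], path) -> None:
    with open(path, "w") as fh:
        for s in annotation_sets:
            genes = "\t".join(sorted(s.member_genes))
            fh.write(f"{s.term_id}\t{s.term_name}\t{genes}\n")


def write_results(results: Sequence[EnrichmentResult], path) -> None:
    import pandas as pd

    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)


def panther_request(query_genes: Iterable[str], annotation_dataset: str) -> dict:
    """Shape a query as an overrepresentation REST request payload.

    Provided as an adapter for users who want to submit the same gene list
    to a hosted annotation service; never exercised by the offline
    pipeline.
    """
    return {
        "geneInputList": ",".join(sorted({g.strip() for g in query_genes})),
        "organism": "9606",
        "annotDataSet": annotation_dataset,
        "enrichmentTestType": "FISHER",
        "correction": "FDR",
    }
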