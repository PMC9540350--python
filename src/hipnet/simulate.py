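"""Seeded synthetic fixtures for every pipeline input.

The generators emulate the shapes of the real inputs — an interaction
catalog with per-observation experimental metadata, STRING-dialect alias
and link files, allelic-series bulk omics with per-gene polyQ trends,
single-nucleus fold changes and single-cell expression fractions, and a
spiked IP-MS design (Q20/Q140 at 2 and 10 months, three replicates per
group) with known differential interactors and stability classes — so the
full pipeline is testable offline. Each generator writes the data files
plus a machine-readable truth manifest; identical specs give identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

SPECIES = ("Human", "Mice", "Rat", "Yeast")
TISSUES = ("brain", "striatum", "cortex", "cerebellum", "liver", "")
HTT_LENGTHS = ("full-length", "fragment", "exon1")
METHODS = ("AP-MS", "Y2H", "co-IP", "XL-MS")
BULK_TISSUES = ("striatum", "cortex", "cerebellum", "hippocampus", "heart",
                "liver")
AGES = (2, 6, 10)
Q_LENGTHS = (50, 80, 92, 111, 140, 175)
CELL_TYPES = ("MSN-D1", "MSN-D2", "astrocyte", "oligodendrocyte",
              "interneuron", "microglia")
IPMS_GROUPS = ("Q20-2M", "Q140-2M", "Q20-10M", "Q140-10M")


@dataclass
class FixtureSpec:
    """All tunables of the synthetic-data generators.

    IP-MS defaults mirror the cortex study design: four genotype-age
    groups with three biological replicates, log-normal abundances with
    sigma(log2) = 0.2, 4-fold (log2 = 2) spiked increases in the Q140
    groups, SAINT scores near 1 for true interactors and near 0.2 for
    decoys, and a 20% stable-class mix (stability ratio near 1 vs near
    0.5 for fast-exchanging interactions).
    """

    seed: int = 0
    n_genes: int = 50
    n_studies: int = 8
    obs_per_gene: float = 3.0
    species: tuple = SPECIES
    tissues: tuple = TISSUES
    htt_lengths: tuple = HTT_LENGTHS
    methods: tuple = METHODS
    confirm_rate: float = 0.85
    # omics
    slope_sd: float = 0.5
    noise_sd: float = 0.1
    # string graph
    edge_probability: float = 0.15
    alias_dropout: float = 0.1
    # ipms
    n_proteins: int = 200
    n_spiked: int = 20
    spike_log2fc: float = 2.0
    noise_sd_log2: float = 0.2
    replicates: int = 3
    saint_true_mean: float = 0.95
    saint_false_mean: float = 0.2
    stable_fraction: float = 0.2
    isotope_noise: float = 0.02


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(n)]


def gen_ppi_catalog(spec: FixtureSpec, out_dir) -> dict:
    """Write a catalog-dialect interaction TSV with known truth sets.

    The manifest records, per metadata field value, the set of genes with
    at least one confirmed observation carrying it, plus the combined
    "mice AND brain" conjunction set used by filter tests.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = _gene_names(spec.n_genes)
    studies = [f"S{i:03d}" for i in range(spec.n_studies)]

    rows = []
    for gene in genes:
        n_obs = 1 + rng.poisson(max(spec.obs_per_gene - 1, 0))
        for _ in range(n_obs):
            species = str(rng.choice(spec.species))
            rows.append(
                {
                    "gene_symbol": gene if species == "Human" else gene.lower(),
                    "study_identifier": str(rng.choice(studies)),
                    "model": species,
                    "model_organism": species,
                    "tissue": str(rng.choice(spec.tissues)),
                    "htt_length": str(rng.choice(spec.htt_lengths)),
                    "detection_method": str(rng.choice(spec.methods)),
                    "common_name": "",
                    "cell_culture_comment": "",
                    "interaction_result": (
                        "Y" if rng.random() < spec.confirm_rate else "N"
                    ),
                }
            )
    columns = [
        "gene_symbol", "study_identifier", "model", "model_organism",
        "tissue", "htt_length", "detection_method", "common_name",
        "cell_culture_comment", "interaction_result",
    ]
    table = pd.DataFrame(rows, columns=columns)
    path = out_dir / "ppi_catalog.tsv"
    table.to_csv(path, sep="\t", index=False)

    # ortholog map: every non-human (lower-case) symbol maps back to the
    # upper-case human symbol with a synthetic Entrez id
    entrez = {g: 100000 + i for i, g in enumerate(genes)}
    map_rows = [
        {"source_organism": sp, "source_symbol": g.lower(),
         "human_symbol": g, "entrez_id": entrez[g]}
        for g in genes for sp in spec.species if sp != "Human"
    ]
    map_path = out_dir / "ortholog_map.tsv"
    pd.DataFrame(map_rows).to_csv(map_path, sep="\t", index=False)

    confirmed = table[table["interaction_result"] == "Y"]
    human_symbol = confirmed["gene_symbol"].str.upper()

    def genes_where(mask) -> list[str]:
        return sorted(set(human_symbol[mask]))

    manifest = {
        "genes": genes,
        "entrez": entrez,
        "confirmed_genes": sorted(set(human_symbol)),
        "by_species": {
            sp: genes_where(confirmed["model_organism"] == sp)
            for sp in spec.species
        },
        "by_tissue": {
            t: genes_where(confirmed["tissue"] == t)
            for t in spec.tissues if t
        },
        "mice_and_brain": genes_where(
            (confirmed["model_organism"] == "Mice")
            & (confirmed["tissue"] == "brain")
        ),
        "study_counts": {
            g: int(n) for g, n in
            confirmed.groupby(human_symbol)["study_identifier"]
            .nunique().items()
        },
    }
    (out_dir / "ppi_manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"table": path, "ortholog_map": map_path, "manifest": manifest}


def gen_string_files(spec: FixtureSpec, genes: list[str], out_dir) -> dict:
    """Write STRING-dialect aliases and links files over synthetic genes.

    A held-out fraction of genes receives no alias row (their Entrez id is
    unresolvable); links are emitted as symmetric directed pairs with
    integer combined scores in [150, 999].
    """
    rng = np.random.default_rng(spec.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entrez = {g: 100000 + i for i, g in enumerate(sorted(genes))}
    string_id = {g: f"9606.ENSP{i:08d}" for i, g in enumerate(sorted(genes))}

    n_drop = int(round(spec.alias_dropout * len(genes)))
    dropped = set(rng.choice(sorted(genes), size=n_drop, replace=False)) \
        if n_drop else set()

    aliases_path = out_dir / "protein.aliases.synthetic.txt"
    with open(aliases_path, "w") as fh:
        fh.write("#string_protein_id\talias\tsource\n")
        for g in sorted(genes):
            if g in dropped:
                continue
            fh.write(f"{string_id[g]}\t{entrez[g]}\tEntrez_Gene_ID\n")
            fh.write(f"{string_id[g]}\t{g}\tgene_symbol\n")

    edges = {}
    resolvable = sorted(set(genes) - dropped)
    for i, a in enumerate(resolvable):
        for b in resolvable[i + 1:]:
            if rng.random() < spec.edge_probability:
                edges[(a, b)] = int(rng.integers(150, 1000))
    links_path = out_dir / "protein.links.synthetic.txt"
    with open(links_path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for (a, b), s in sorted(edges.items()):
            fh.write(f"{string_id[a]} {string_id[b]} {s}\n")
            fh.write(f"{string_id[b]} {string_id[a]} {s}\n")

    manifest = {
        "entrez": entrez,
        "dropped": sorted(dropped),
        "edges": [[a, b, s] for (a, b), s in sorted(edges.items())],
    }
    (out_dir / "string_manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"aliases": aliases_path, "links": links_path, "manifest": manifest}


def gen_omics(spec: FixtureSpec, genes: list[str], out_dir) -> dict:
    """Write bulk, single-nucleus and single-cell omics tables.

    Bulk log2 ratios follow a per-gene linear polyQ trend
    slope_g * (Q - 20) / 155 plus Gaussian noise, emitted per sex so
    the averaging step is exercised; the Q50 x 2-month combination is
    absent, as in the allelic-series design. Single-nucleus fold changes
    are drawn around a per-cell-type mean and single-cell fractions from
    a Beta distribution. True slopes are recorded in the manifest.
    """
    rng = np.random.default_rng(spec.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = sorted(genes)
    slopes = {g: float(rng.normal(0.0, spec.slope_sd)) for g in genes}

    bulk_rows = []
    for g in genes:
        for modality in ("bulk_rna", "bulk_protein"):
            for tissue in BULK_TISSUES:
                for age in AGES:
                    for q in Q_LENGTHS:
                        if q == 50 and age == 2:
                            continue
                        base = slopes[g] * (q - 20) / 155.0
                        for sex in ("M", "F"):
                            bulk_rows.append(
                                {
                                    "gene_symbol_human": g,
                                    "modality": modality,
                                    "tissue": tissue,
                                    "age_months": age,
                                    "q_length": q,
                                    "sex": sex,
                                    "value": base + float(
                                        rng.normal(0.0, spec.noise_sd)
                                    ),
                                }
                            )
    bulk_path = out_dir / "bulk_omics.tsv"
    pd.DataFrame(bulk_rows).to_csv(bulk_path, sep="\t", index=False)

    ct_means = {ct: float(rng.normal(0.0, 0.2)) for ct in CELL_TYPES}
    sn_rows = [
        {"gene_symbol_human": g, "cell_type": ct,
         "value": ct_means[ct] + float(rng.normal(0.0, spec.noise_sd))}
        for g in genes for ct in CELL_TYPES
    ]
    sn_path = out_dir / "snrna_fc.tsv"
    pd.DataFrame(sn_rows).to_csv(sn_path, sep="\t", index=False)

    sc_rows = [
        {"gene_symbol_human": g, "cell_type": ct,
         "value": float(rng.beta(2.0, 2.0))}
        for g in genes for ct in CELL_TYPES
    ]
    sc_path = out_dir / "scrna_fraction.tsv"
    pd.DataFrame(sc_rows).to_csv(sc_path, sep="\t", index=False)

    manifest = {"slopes": slopes, "cell_type_means": ct_means}
    (out_dir / "omics_manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"bulk": bulk_path, "snrna": sn_path, "scrna": sc_path,
            "manifest": manifest}


def gen_ipms(spec: FixtureSpec, out_dir) -> dict:
    """Write a spiked IP-MS abundance matrix, SAINT table and isotope table.

    Proteins are log-normal with sigma(log2) = ``noise_sd_log2``; the
    first ``n_spiked`` proteins carry a ``spike_log2fc`` increase in the
    Q140 groups. True interactors (spiked) draw SAINT scores near
    ``saint_true_mean``; decoys near ``saint_false_mean``. Each protein
    is assigned a stability class (stable -> light/(light+heavy) near 1,
    exchanging -> near 0.5) recorded in the manifest. The bait row "HTT"
    varies across samples so bait normalization is non-trivial.
    """
    rng = np.random.default_rng(spec.seed + 3)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteins = [f"PROT{i:04d}" for i in range(spec.n_proteins)]
    spiked = proteins[: spec.n_spiked]
    samples = [
        f"{g}_r{r + 1}" for g in IPMS_GROUPS for r in range(spec.replicates)
    ]

    base_log2 = {p: float(rng.uniform(18, 26)) for p in proteins}
    bait_log2 = {s: float(rng.normal(24.0, 0.3)) for s in samples}
    mean_bait = float(np.mean([2.0 ** v for v in bait_log2.values()]))

    data = {}
    for s in samples:
        group = s.rsplit("_", 1)[0]
        is_q140 = group.startswith("Q140")
        bait_factor = (2.0 ** bait_log2[s]) / mean_bait
        col = []
        for p in proteins:
            mu = base_log2[p]
            if is_q140 and p in spiked:
                mu += spec.spike_log2fc
            val = 2.0 ** (mu + float(rng.normal(0.0, spec.noise_sd_log2)))
            col.append(val * bait_factor)
        data[s] = col
    matrix = pd.DataFrame(data, index=proteins)
    matrix.loc["HTT"] = [2.0 ** bait_log2[s] for s in samples]
    abundances_path = out_dir / "ipms_abundances.tsv"
    matrix.to_csv(abundances_path, sep="\t", index_label="protein")

    saint_rows = []
    for p in proteins:
        true_int = p in spiked
        mean = spec.saint_true_mean if true_int else spec.saint_false_mean
        for g in IPMS_GROUPS:
            for r in range(spec.replicates):
                score = float(np.clip(rng.normal(mean, 0.05), 0.0, 1.0))
                saint_rows.append(
                    {"protein": p, "group": g, "replicate": r + 1,
                     "saint_score": score}
                )
    saint_path = out_dir / "ipms_saint.tsv"
    pd.DataFrame(saint_rows).to_csv(saint_path, sep="\t", index=False)

    stable = set(
        rng.choice(
            proteins,
            size=int(round(spec.stable_fraction * spec.n_proteins)),
            replace=False,
        )
    )
    iso_rows = []
    for p in proteins:
        target = 1.0 if p in stable else 0.5
        for g in ("Q20-2M", "Q140-2M"):
            ratio = float(
                np.clip(target + rng.normal(0.0, spec.isotope_noise), 0.01, 1.0)
            )
            light = 1e6 * ratio
            heavy = 1e6 * (1.0 - ratio)
            iso_rows.append(
                {"protein": p, "group": g, "light_intensity": light,
                 "heavy_intensity": heavy}
            )
    iso_path = out_dir / "ipms_isotopes.tsv"
    pd.DataFrame(iso_rows).to_csv(iso_path, sep="\t", index=False)

    manifest = {
        "proteins": proteins,
        "spiked": spiked,
        "spike_log2fc": spec.spike_log2fc,
        "stable": sorted(stable),
        "bait": "HTT",
    }
    (out_dir / "ipms_manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "abundances": abundances_path,
        "saint": saint_path,
        "isotopes": iso_path,
        "manifest": manifest,
    }


def generate_all(spec: FixtureSpec, out_dir) -> dict:
    """Run every generator into one directory; returns all paths/manifests."""
    out_dir = Path(out_dir)
    ppi = gen_ppi_catalog(spec, out_dir)
    genes = ppi["manifest"]["genes"]
    return {
        "ppi": ppi,
        "string": gen_string_files(spec, genes, out_dir),
        "omics": gen_omics(spec, genes, out_dir),
        "ipms": gen_ipms(spec, out_dir),
        "spec": asdict(spec),
    }
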