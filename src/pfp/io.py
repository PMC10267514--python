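"""Readers and writers for the external formats the pipeline touches.

All protein coordinates are 1-based inclusive (UniProt convention). Quant
matrices follow the MaxQuant proteinGroups convention: for LFQ intensities an
empty cell or a literal 0 both mean "not quantified"; for spectral counts 0 is
a true zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("pfp")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "U"}
SOURCE_CLASSES = ("canonical", "isoform", "riboseq")
FEATURE_TYPES = (
    "signal",
    "transit",
    "propeptide",
    "domain",
    "region",
    "motif",
    "coiled_coil",
    "zinc_finger",
    "repeat",
    "compositional_bias",
)

#: Required columns of a PeptideTable, in canonical order.  ``accessions`` is a
#: semicolon-joined string; ``riboseq_region`` is one of cds/utr5/ntr/n/a.
PEPTIDE_COLUMNS = [
    "sequence",
    "accessions",
    "start",
    "nterm_mod",
    "protease",
    "spectral_count",
    "acetylation_fraction",
    "riboseq_support",
    "start_codon",
    "in_5utr",
    "riboseq_region",
]

NTERM_MODS = ("acetyl_in_vivo", "acetyl_heavy", "pyroglutamate", "none")

QUANT_FLAG_COLUMNS = ["reverse", "contaminant", "only_identified_by_site"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteomeEntry:
    sequence: str
    source_class: str
    gene: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeDB:
    """In-memory proteome: accession -> (sequence, source class, gene)."""

    entries: dict[str, ProteomeEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __getitem__(self, accession: str) -> ProteomeEntry:
        return self.entries[accession]

    def add(self, accession: str, sequence: str, source_class: str, gene: str) -> None:
        if accession in self.entries:
            raise FormatError(f"duplicate accession {accession!r}")
        if source_class not in SOURCE_CLASSES:
            raise FormatError(f"unknown source class {source_class!r} for {accession!r}")
        sequence = sequence.upper()
        if not sequence:
            raise FormatError(f"empty sequence for {accession!r}")
        bad = set(sequence) - AMINO_ACIDS
        if bad:
            raise FormatError(f"invalid residues {sorted(bad)} in {accession!r}")
        self.entries[accession] = ProteomeEntry(sequence, source_class, gene)

    def accessions(self) -> list[str]:
        return list(self.entries)

    def canonical_sequences(self) -> list[str]:
        return [e.sequence for e in self.entries.values() if e.source_class == "canonical"]


@dataclass
class QuantMatrix:
    """Proteins x samples quantification matrix with row flags and groups.

    ``values`` holds floats with NaN for missing; ``flags`` holds the
    reverse / contaminant / only_identified_by_site booleans per protein;
    ``groups`` maps sample name -> group (bait / tissue) label.
    """

    values: pd.DataFrame
    genes: pd.Series
    flags: pd.DataFrame
    groups: pd.Series
    value_kind: str = "lfq"

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            self.values.copy(), self.genes.copy(), self.flags.copy(),
            self.groups.copy(), self.value_kind,
        )

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_fasta(path: str | Path) -> ProteomeDB:
    """Load a proteome FASTA with ``>accession|source_class|gene`` headers.

    Lowercase sequences are normalized to uppercase with a logged warning;
    duplicate accessions and malformed headers are rejected.
    """
    path = Path(path)
    db = ProteomeDB()
    n_lower = 0
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.description.split("|")
        if len(parts) != 3:
            raise FormatError(
                f"{path}: malformed header {record.description!r} "
                "(expected accession|source_class|gene)"
            )
        accession, source_class, gene = (p.strip() for p in parts)
        seq = str(record.seq)
        if seq != seq.upper():
            n_lower += 1
        db.add(accession, seq, source_class, gene)
    if n_lower:
        logger.warning("read_fasta: normalized %d lowercase sequences to uppercase", n_lower)
    if len(db) == 0:
        raise FormatError(f"{path}: no FASTA records found")
    logger.info("read_fasta: %d records from %s", len(db), path)
    return db


def write_fasta(db: ProteomeDB, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=f"{acc}|{e.source_class}|{e.gene}", description="")
        for acc, e in db.entries.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    # keep_default_na=False preserves the literal "n/a" riboseq_region value
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing peptide-table columns {missing}")
    if (df["start"] < 1).any():
        raise FormatError(f"{path}: start positions must be >= 1")
    if (df["spectral_count"] < 0).any():
        raise FormatError(f"{path}: spectral counts must be >= 0")
    df["riboseq_support"] = df["riboseq_support"].astype(bool)
    df["in_5utr"] = df["in_5utr"].astype(bool)
    logger.info("read_peptide_table: %d rows from %s", len(df), path)
    return df


def write_peptide_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path, proteome: ProteomeDB | None = None) -> pd.DataFrame:
    """Feature ranges (1-based inclusive) per accession; validated on load."""
    df = pd.read_csv(path, sep="\t")
    required = ["accession", "feature_type", "start", "end", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing feature-table columns {missing}")
    unknown = set(df["feature_type"]) - set(FEATURE_TYPES)
    if unknown:
        raise FormatError(f"{path}: unknown feature types {sorted(unknown)}")
    if ((df["start"] < 1) | (df["end"] < df["start"])).any():
        raise FormatError(f"{path}: feature ranges must satisfy 1 <= start <= end")
    if proteome is not None:
        for _, row in df.iterrows():
            if row["accession"] in proteome:
                if row["end"] > proteome[row["accession"]].length:
                    raise FormatError(
                        f"{path}: feature {row['label']!r} exceeds length of "
                        f"{row['accession']}"
                    )
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_known_interactions(path: str | Path) -> pd.DataFrame:
    """Unordered gene-symbol pairs, each tagged with a source database."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_a", "gene_b", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing interaction columns {missing}")
    if (df["gene_a"].astype(str).str.len() == 0).any() or (
        df["gene_b"].astype(str).str.len() == 0
    ).any():
        raise FormatError(f"{path}: empty gene symbols")
    self_pairs = df["gene_a"] == df["gene_b"]
    if self_pairs.any():
        logger.warning("read_known_interactions: %d self-pairs", int(self_pairs.sum()))
    return df


def interaction_pairs(known: pd.DataFrame) -> set[frozenset]:
    return {frozenset((a, b)) for a, b in zip(known["gene_a"], known["gene_b"])}


def partners_of(known: pd.DataFrame, gene: str) -> set[str]:
    """Known interaction partners of ``gene`` (symbols on the other side)."""
    mask_a = known["gene_a"] == gene
    mask_b = known["gene_b"] == gene
    return set(known.loc[mask_a, "gene_b"]) | set(known.loc[mask_b, "gene_a"])


def read_quant_matrix(
    path: str | Path,
    value_kind: str = "lfq",
    zero_is_missing: bool | None = None,
) -> QuantMatrix:
    """Read a MaxQuant proteinGroups-like TSV subset.

    Expected columns: ``accession``, ``gene``, optional ``group:<sample>``
    metadata row encoded as a ``group_<sample>``-free design — here the group
    of each sample column is declared in a ``#groups`` comment line or via
    ``sample=group`` column headers of the form ``<group>|<sample>``.
    Remaining columns are per-sample values; optional boolean flag columns
    ``reverse`` / ``contaminant`` / ``only_identified_by_site`` are preserved.
    """
    if value_kind not in ("lfq", "spectral_count"):
        raise ValueError(f"unknown value_kind {value_kind!r}")
    if zero_is_missing is None:
        zero_is_missing = value_kind == "lfq"
    df = pd.read_csv(path, sep="\t")
    if "accession" not in df.columns or "gene" not in df.columns:
        raise FormatError(f"{path}: need 'accession' and 'gene' columns")
    if df["accession"].duplicated().any():
        dups = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise FormatError(f"{path}: duplicate accession rows {dups[:5]}")
    df = df.set_index("accession")
    genes = df.pop("gene")
    flags = pd.DataFrame(False, index=df.index, columns=QUANT_FLAG_COLUMNS)
    for col in QUANT_FLAG_COLUMNS:
        if col in df.columns:
            raw = df.pop(col)
            flags[col] = raw.notna() & raw.astype(str).str.lower().isin(
                ["true", "yes", "+", "1"]
            )
    sample_cols = list(df.columns)
    groups = {}
    renamed = {}
    for col in sample_cols:
        if "|" in col:
            group, sample = col.split("|", 1)
        else:
            group, sample = col, col
        groups[sample] = group
        renamed[col] = sample
    values = df.rename(columns=renamed)
    try:
        values = values.astype(float)
    except ValueError as exc:
        for col in values.columns:
            bad = pd.to_numeric(values[col], errors="coerce").isna() & values[col].notna()
            if bad.any():
                row = values.index[bad.argmax()]
                raise FormatError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                ) from exc
        raise
    if zero_is_missing:
        values = values.mask(values == 0)
    logger.info(
        "read_quant_matrix: %d proteins x %d samples from %s (%s)",
        values.shape[0], values.shape[1], path, value_kind,
    )
    return QuantMatrix(values, genes, flags, pd.Series(groups), value_kind)


def write_quant_matrix(matrix: QuantMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.columns = [f"{matrix.groups[s]}|{s}" for s in out.columns]
    out.insert(0, "gene", matrix.genes)
    for col in QUANT_FLAG_COLUMNS:
        out[col] = matrix.flags[col]
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


def write_edge_list(network: nx.MultiGraph, path: str | Path, format: str = "tsv") -> None:
    """Export a PPI network; one edge per line/element with its source method."""
    path = Path(path)
    if format == "tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "method": key,
                "db_support": data.get("db_support", False),
            }
            for u, v, key, data in network.edges(keys=True, data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "method", "db_support"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, key in network.edges(keys=True):
                fh.write(f"{u}\t{key}\t{v}\n")
    elif format == "graphml":
        g = nx.MultiGraph()
        for n, data in network.nodes(data=True):
            g.add_node(n, **{k: str(v) for k, v in data.items()})
        for u, v, key, data in network.edges(keys=True, data=True):
            g.add_edge(u, v, key=key, **{k: str(v) for k, v in data.items()})
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown edge-list format {format!r}")


def read_edge_list(path: str | Path) -> nx.MultiGraph:
    df = pd.read_csv(path, sep="\t")
    g = nx.MultiGraph()
    for _, row in df.iterrows():
        g.add_edge(
            row["source"], row["target"], key=row["method"],
            db_support=bool(row["db_support"]),
        )
    return g


def data_path(name: str) -> Path:
    """Path of a bundled data table (worked-example candidate tables)."""
    from importlib import resources

    return Path(str(resources.files("pfp") / "data" / name))


def read_candidate_flags(path: str | Path) -> pd.DataFrame:
    """Read a printed candidate-interactor table (FL / PR yes-flags per prey
    gene, with optional database-support and cross-method columns)."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise FormatError(f"{path}: need a 'gene' column")
    for col in ("fl", "pr", "ppi_databases", "virotrap"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str).str.lower() == "yes"
    return df


DEFAULT_CONFIG: dict = {
    "catalog": {
        "imet_small_residues": list("ACGPSTV"),
        "acetylation_high_threshold": 0.5,
    },
    "annotate": {
        "identity_floor": 0.3,
        "gap_open": -9.5,
        "gap_extend": -0.5,
        "processing_margin": 1,
        "dipeptidase_max_removed": 8,
    },
    "score": {
        "gene_score_threshold": 0,
        "long_protein_length": 700,
        "min_truncation": 20,
        "min_truncation_long": 50,
    },
    "tissue": {
        "psm_q_threshold": 0.01,
        "fdr_threshold": 0.05,
    },
    "interactome": {
        "min_valid_per_group": 3,
        "candidate_fdr": 0.01,
        "differential_fdr": 0.05,
        "fc_threshold": 1.0,
        "imputation": "qrilc_like",
        "shift": 1.8,
        "spread": 0.3,
        "fdr_method": "bh",
        "n_imputation_draws": 1,
    },
    "simulate": {
        "n_genes": 200,
        "proteoform_rate": 0.3,
        "extension_rate": 0.06,
        "length_range": [50, 2000],
    },
}


def _deep_update(base: dict, update: Mapping) -> dict:
    for key, value in update.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None) -> dict:
    """YAML config with one section per pipeline stage; unset keys default."""
    import copy

    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(config, user)
    return config
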