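"""Classification of identified N-terminal peptides into a proteoform catalogue.

N-terminal peptides starting at position 1 or 2 of their matched protein point
to the database-annotated translation start; peptides starting beyond position
2 point to alternative translation initiation (an N-terminal proteoform).
Starts at position 2 are additionally checked against initiator-methionine
(iMet) processing: methionine aminopeptidases remove the iMet only when the
second residue is small ({A, C, G, P, S, T, V}).  Alternative starts get a
high/low confidence level from co-translational Nt-acetylation and orthogonal
Ribo-seq evidence, per-protease catalogues are merged into unique N-termini,
and the catalogue is tabulated by source class x start class x confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import ProteomeDB

IMET_SMALL_RESIDUES = frozenset("ACGPSTV")

SOURCE_PRIORITY = {"canonical": 0, "isoform": 1, "riboseq": 2}


@dataclass
class ProteoformRecord:
    accession: str
    gene: str
    source_class: str
    start_class: str            # database_annotated / alternative
    riboseq_region: str         # cds / utr5 / ntr / n/a
    confidence: str             # high / low / n/a
    start: int
    offset_vs_canonical: int    # residues; negative = extension
    supporting_peptides: list[str] = field(default_factory=list)
    proteases_observed: set[str] = field(default_factory=set)
    spectral_count: int = 0


def classify_start(
    start: int,
    protein_sequence: str,
    imet_small: frozenset = IMET_SMALL_RESIDUES,
) -> tuple[str, str]:
    """Classify a peptide start as database-annotated vs alternative.

    Returns ``(start_class, imet_status)``.  Start 1 or 2 is
    database-annotated; start 2 is checked against the MetAP rule (second
    residue small -> iMet removal expected).  For alternative starts the same
    logic applies relative to the proteoform's own initiator: a start at an
    internal Met is compliant, and a start one residue after an internal Met
    is compliant iff the started residue is small.
    """
    if start < 1:
        raise ValueError("start must be >= 1")
    if start > len(protein_sequence):
        raise ValueError(
            f"start {start} beyond protein length {len(protein_sequence)}"
        )
    if start == 1:
        return "database_annotated", "compliant"
    residue = protein_sequence[start - 1]
    preceded_by_met = protein_sequence[start - 2] == "M"
    if start == 2:
        status = "compliant" if residue in imet_small else "noncompliant"
        return "database_annotated", status
    if residue == "M":
        return "alternative", "compliant"
    if preceded_by_met:
        status = "compliant" if residue in imet_small else "noncompliant"
        return "alternative", status
    return "alternative", "noncompliant"


def assign_confidence(
    acetylation_fraction: float,
    riboseq_support: bool,
    imet_status: str,
    acetylation_threshold: float = 0.5,
) -> str:
    """High/low confidence for an alternative start.

    High iff the N-terminus is mostly in-vivo acetylated (fraction above the
    threshold) or has Ribo-seq support at an iMet-compliant start.  Free
    (heavy-acetyl) N-termini with a compliant iMet context but no orthogonal
    evidence stay low.
    """
    if acetylation_fraction > acetylation_threshold:
        return "high"
    if riboseq_support and imet_status == "compliant":
        return "high"
    return "low"


def sort_accessions(
    accessions: list[str],
    proteome: ProteomeDB,
    peptide_counts: dict[str, int] | None = None,
    starts: dict[str, int] | None = None,
) -> list[str]:
    """Order multi-mapping accessions by the cataloguing priority.

    UniProt canonical first, then UniProt isoforms, then Ribo-seq entries;
    within a class, higher peptide count (in the whole sample) first, then
    smallest start position, then accession alphabetically.
    """
    peptide_counts = peptide_counts or {}
    starts = starts or {}

    def key(acc: str):
        entry = proteome[acc]
        return (
            SOURCE_PRIORITY[entry.source_class],
            -peptide_counts.get(acc, 0),
            starts.get(acc, 1),
            acc,
        )

    return sorted(accessions, key=key)


_MOD_PRIORITY = {"acetyl_in_vivo": 0, "acetyl_heavy": 1, "pyroglutamate": 2, "none": 3}


def merge_catalogs(
    peptide_tables: list[pd.DataFrame],
    proteome: ProteomeDB,
) -> pd.DataFrame:
    """Merge per-protease peptide tables into unique N-termini.

    One row per unique (primary accession, start).  Modification conflicts
    resolve in favour of in-vivo acetylated peptides; accession lists of
    multi-mapping peptides are sorted by the cataloguing priority and the
    first is retained as primary; proteases are unioned and spectral counts
    summed.
    """
    if not peptide_tables:
        return pd.DataFrame()
    df = pd.concat(peptide_tables, ignore_index=True).copy()

    all_accessions = {
        acc for accs in df["accessions"] for acc in str(accs).split(";")
    }
    unknown = all_accessions - set(proteome.accessions())
    if unknown:
        raise ValueError(f"catalog references unknown accessions {sorted(unknown)[:5]}")

    # whole-sample peptide count per accession (for the sort priority)
    counts: dict[str, int] = {}
    for accs in df["accessions"]:
        for acc in str(accs).split(";"):
            counts[acc] = counts.get(acc, 0) + 1

    df["primary_accession"] = [
        sort_accessions(str(accs).split(";"), proteome, counts)[0]
        for accs in df["accessions"]
    ]
    df["_mod_rank"] = df["nterm_mod"].map(_MOD_PRIORITY)

    merged_rows = []
    for (acc, start), group in df.groupby(["primary_accession", "start"], sort=True):
        group = group.sort_values(["_mod_rank", "sequence"], kind="stable")
        top = group.iloc[0]
        total_sc = int(group["spectral_count"].sum())
        # acetylation fraction pooled over PSMs of this N-terminus
        frac = float(
            (group["acetylation_fraction"] * group["spectral_count"]).sum()
            / max(total_sc, 1)
        )
        merged_rows.append({
            "sequence": top["sequence"],
            "accessions": ";".join(
                sort_accessions(
                    sorted({a for accs in group["accessions"]
                            for a in str(accs).split(";")}),
                    proteome, counts,
                )
            ),
            "primary_accession": acc,
            "start": int(start),
            "nterm_mod": top["nterm_mod"],
            "protease": ";".join(sorted(set(group["protease"]))),
            "spectral_count": total_sc,
            "acetylation_fraction": frac,
            "riboseq_support": bool(group["riboseq_support"].any()),
            "start_codon": top["start_codon"],
            "in_5utr": bool(top["in_5utr"]),
            "riboseq_region": top["riboseq_region"],
        })
    return pd.DataFrame(merged_rows)


def classify_catalog(
    merged: pd.DataFrame,
    proteome: ProteomeDB,
    acetylation_threshold: float = 0.5,
    imet_small: frozenset = IMET_SMALL_RESIDUES,
) -> list[ProteoformRecord]:
    """Turn a merged peptide table into classified ProteoformRecords."""
    records = []
    for _, row in merged.iterrows():
        acc = row["primary_accession"]
        entry = proteome[acc]
        start = int(row["start"])
        start_class, imet_status = classify_start(start, entry.sequence, imet_small)
        if start_class == "alternative":
            confidence = assign_confidence(
                float(row["acetylation_fraction"]),
                bool(row["riboseq_support"]),
                imet_status,
                acetylation_threshold,
            )
        else:
            confidence = "n/a"
        region = row.get("riboseq_region", "n/a")
        if entry.source_class != "riboseq":
            region = "n/a"
        records.append(ProteoformRecord(
            accession=acc,
            gene=entry.gene,
            source_class=entry.source_class,
            start_class=start_class,
            riboseq_region=region,
            confidence=confidence,
            start=start,
            offset_vs_canonical=start - 1 if start_class == "alternative" else 0,
            supporting_peptides=[row["sequence"]],
            proteases_observed=set(str(row["protease"]).split(";")),
            spectral_count=int(row["spectral_count"]),
        ))
    return records


def tabulate_taxonomy(records: list[ProteoformRecord]) -> pd.DataFrame:
    """Tabulate catalogue counts in the published taxonomy layout.

    Detail cells: per source class, database-annotated vs alternative counts
    and the high/low confidence split of the alternative starts; for Ribo-seq
    entries the region split (TIS in annotated CDS / 5'UTR / NTR).  Summary
    rows: the database-annotated TIS total counts canonical
    database-annotated starts only, while the alternative TIS total counts
    canonical alternative starts plus ALL isoform-only and ALL riboseq-only
    N-termini; the grand total is the sum of everything.
    """
    def count(pred) -> int:
        return sum(1 for r in records if pred(r))

    rows = [
        ("uniprot_total", count(lambda r: r.source_class == "canonical")),
        ("uniprot_database_annotated",
         count(lambda r: r.source_class == "canonical"
               and r.start_class == "database_annotated")),
        ("uniprot_alternative",
         count(lambda r: r.source_class == "canonical"
               and r.start_class == "alternative")),
        ("uniprot_alternative_high",
         count(lambda r: r.source_class == "canonical"
               and r.start_class == "alternative" and r.confidence == "high")),
        ("uniprot_alternative_low",
         count(lambda r: r.source_class == "canonical"
               and r.start_class == "alternative" and r.confidence == "low")),
        ("isoform_total", count(lambda r: r.source_class == "isoform")),
        ("isoform_database_annotated",
         count(lambda r: r.source_class == "isoform"
               and r.start_class == "database_annotated")),
        ("isoform_alternative",
         count(lambda r: r.source_class == "isoform"
               and r.start_class == "alternative")),
        ("isoform_alternative_high",
         count(lambda r: r.source_class == "isoform"
               and r.start_class == "alternative" and r.confidence == "high")),
        ("isoform_alternative_low",
         count(lambda r: r.source_class == "isoform"
               and r.start_class == "alternative" and r.confidence == "low")),
        ("riboseq_total", count(lambda r: r.source_class == "riboseq")),
        ("riboseq_cds",
         count(lambda r: r.source_class == "riboseq" and r.riboseq_region == "cds")),
        ("riboseq_utr5",
         count(lambda r: r.source_class == "riboseq" and r.riboseq_region == "utr5")),
        ("riboseq_ntr",
         count(lambda r: r.source_class == "riboseq" and r.riboseq_region == "ntr")),
    ]
    total = len(records)
    db_annotated = count(lambda r: r.source_class == "canonical"
                         and r.start_class == "database_annotated")
    alternative = (
        count(lambda r: r.source_class == "canonical"
              and r.start_class == "alternative")
        + count(lambda r: r.source_class == "isoform")
        + count(lambda r: r.source_class == "riboseq")
    )
    rows += [
        ("total", total),
        ("database_annotated_tis", db_annotated),
        ("alternative_tis", alternative),
    ]
    return pd.DataFrame(rows, columns=["category", "count"]).set_index("category")
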