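"""Additive evidence scoring of alternative translation initiation sites.

Each alternative proteoform gets a TIS score: eleven binary evidence items
(confidence, >50% Nt-acetylation, spectral count > 1, several peptides
pointing to the same start, database/Ribo-seq support for the TIS, multiple
proteases, a non-AUG start in the 5'UTR, a lost or gained linear motif,
presence in an earlier N-terminomics compendium, an OMIM disease link, no
known interactions) each add 1; truncation of less than half the protein and
a lost annotated domain each add 3; any suspicion that the N-terminus stems
from proteolytic processing (signal/transit/propeptide removal, dipeptidase
trimming, a known protease cleavage site) traps the score at 0.  Gene scores
sum the proteoform scores and are retained only for gene categories where an
alternative start coexists with (or replaces) the annotated one.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

#: The eleven evidence items worth +1 each, in their conventional order.
PLUS_ONE_ITEMS = (
    "high_confident",
    "acetylation_gt_50",
    "spectral_count_gt_1",
    "multiple_peptides_same_tis",
    "db_or_riboseq_tis",
    "multi_protease",
    "non_aug_in_5utr",
    "elm_lost_or_gained",
    "in_vandamme_2014",
    "omim_disease",
    "no_biogrid_interactions",
)
PLUS_THREE_ITEMS = ("truncation_lt_half", "uniprot_domain_lost")


@dataclass(frozen=True)
class EvidenceVector:
    high_confident: bool = False
    acetylation_gt_50: bool = False
    spectral_count_gt_1: bool = False
    multiple_peptides_same_tis: bool = False
    db_or_riboseq_tis: bool = False
    multi_protease: bool = False
    non_aug_in_5utr: bool = False
    elm_lost_or_gained: bool = False
    in_vandamme_2014: bool = False
    omim_disease: bool = False
    no_biogrid_interactions: bool = False
    truncation_lt_half: bool = False
    uniprot_domain_lost: bool = False
    processing_suspected: bool = False


EVIDENCE_FIELDS = tuple(f.name for f in fields(EvidenceVector))


@dataclass
class TisScore:
    score: int
    contributions: list[tuple[str, int]]
    zero_trap: bool = False


def compute_tis_score(evidence: EvidenceVector) -> TisScore:
    """TIS score: sum of +1 and +3 evidence items, zero-trapped by processing.

    Any evidence pattern with ``processing_suspected`` scores 0 regardless of
    the other items.
    """
    if evidence.processing_suspected:
        return TisScore(0, [("processing_suspected", 0)], zero_trap=True)
    contributions = [
        (item, 1) for item in PLUS_ONE_ITEMS if getattr(evidence, item)
    ] + [
        (item, 3) for item in PLUS_THREE_ITEMS if getattr(evidence, item)
    ]
    return TisScore(sum(inc for _, inc in contributions), contributions)


def classify_gene_category(
    start_classes: list[str],
) -> int:
    """Gene category from the start classes of its proteoforms.

    1: annotated + alternative TIS; 2: multiple alternative TIS; 3: multiple
    annotated TIS; 4: one TIS.  Ties resolve in the listed order.
    """
    if not start_classes:
        raise ValueError("need at least one proteoform record")
    n_annotated = sum(1 for s in start_classes if s == "database_annotated")
    n_alternative = sum(1 for s in start_classes if s == "alternative")
    if n_annotated >= 1 and n_alternative >= 1:
        return 1
    if n_alternative >= 2:
        return 2
    if n_annotated >= 2:
        return 3
    return 4


def gene_score(
    tis_scores: list[int],
    category: int,
    cytosolic_evidence: bool = False,
    threshold: int = 0,
) -> tuple[int, bool]:
    """Sum of the gene's alternative-proteoform TIS scores plus retention.

    Retained iff the category is 1 or 2, or 4 with orthogonal cytosolic
    evidence, and the summed score exceeds ``threshold`` (the published
    analysis uses both >0 and >1; >0 is the default).
    """
    score = int(sum(tis_scores))
    retained = category in (1, 2) or (category == 4 and cytosolic_evidence)
    retained = retained and score > threshold
    return score, retained


#: Ordered prioritization criteria (all interpreted "higher/True is better").
PRIORITIZE_CRITERIA = (
    "extra_evidence",
    "domain_elm_delta",
    "length_criterion",
    "cytosolic_evidence_count",
    "non_structural",
    "disease_associated",
    "in_frame",
)


def length_criterion(
    delta_length: int,
    reference_length: int,
    min_truncation: int = 20,
    min_truncation_long: int = 50,
    long_protein_length: int = 700,
) -> bool:
    """Is the truncation/extension long enough to matter?

    More than 20 residues, or more than 50 for proteins over 700 residues.
    """
    cut = min_truncation_long if reference_length > long_protein_length else min_truncation
    return abs(delta_length) > cut


def prioritize(genes: pd.DataFrame, config: dict | None = None) -> pd.DataFrame:
    """Rank retained genes lexicographically over the ordered criteria.

    ``genes`` needs one row per gene with the criterion columns (booleans or
    counts; missing columns default to False / 0 — e.g. structural class
    defaults to non-structural when not annotated), a ``gene_score`` column
    and a ``gene`` symbol column.  Gene score breaks ties, then the symbol.
    """
    config = config or {}
    df = genes.copy()
    defaults = {c: False for c in PRIORITIZE_CRITERIA}
    defaults["cytosolic_evidence_count"] = 0
    defaults["non_structural"] = True
    for col, default in defaults.items():
        if col not in df.columns:
            df[col] = default
    if "length_criterion" not in genes.columns and {
        "delta_length", "reference_length"
    } <= set(df.columns):
        df["length_criterion"] = [
            length_criterion(
                int(d), int(L),
                config.get("min_truncation", 20),
                config.get("min_truncation_long", 50),
                config.get("long_protein_length", 700),
            )
            for d, L in zip(df["delta_length"], df["reference_length"])
        ]
    sort_cols = list(PRIORITIZE_CRITERIA) + ["gene_score", "gene"]
    ascending = [False] * (len(PRIORITIZE_CRITERIA) + 1) + [True]
    ranked = df.sort_values(sort_cols, ascending=ascending, kind="stable")
    ranked = ranked.reset_index(drop=True)
    ranked.insert(0, "rank", range(1, len(ranked) + 1))
    return ranked
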