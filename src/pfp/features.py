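"""Locating proteoforms in their reference proteins and deriving the sequence
regions (and annotated features / linear motifs) they lose or gain.

Truncated proteoforms lose the reference range [1, start-1]; 5'-extended
proteoforms gain their prepended prefix and, because the extension displaces
the reference N-terminus, any feature spanning reference position 1 or 2 is
counted as lost (no longer N-terminal).  Proteoforms that are not an exact
substring of the reference are placed by a BLOSUM62 overlap alignment with
affine gaps (open -9.5, extend -0.5, free end gaps); below an identity floor
the proteoform is reported as having no reliable reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

# Average residue masses (Da); X is the unweighted mean of the 20 residues.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
    "U": 150.0379,
}
AVERAGE_RESIDUE_MASS["X"] = sum(
    AVERAGE_RESIDUE_MASS[a] for a in "GASPVTCLINDQKEMHFRYW"
) / 20.0
WATER_MASS = 18.01528

#: Small built-in ELM-style motif regex table used for gained/lost motif
#: scanning when the user supplies none.
BUILTIN_MOTIFS = {
    "LIG_SH3_CLASSII": r"P..P",
    "DEG_APCC_DBOX": r"R..L..[LIVM]",
    "MOD_CK2_PHOS": r"[ST]..E",
    "LIG_RGD_INTEGRIN": r"RGD",
    "LIG_TRAF2_BINDING": r"[PSAT].[QE]E",
    "MOD_N_MYRISTOYL": r"^MG",
}


@dataclass
class AlignmentResult:
    mode: str                       # exact_substring / overlap_alignment / none
    reference_accession: str
    ref_span: tuple[int, int]       # 1-based inclusive span on reference
    query_span: tuple[int, int]     # 1-based inclusive span on proteoform
    score: float
    identity: float
    proteoform_seq: str = ""
    reference_seq: str = ""


@dataclass
class RegionDelta:
    lost: list[tuple[int, int]] = field(default_factory=list)
    gained: list[tuple[int, int]] = field(default_factory=list)
    lost_features: list[tuple[str, float]] = field(default_factory=list)
    lost_motifs: list[str] = field(default_factory=list)
    gained_motifs: list[str] = field(default_factory=list)


@dataclass
class ProcessingFlags:
    signal_transit_propeptide: bool = False
    processing_distance: int | None = None
    dipeptidase: bool = False
    known_protease_site: bool = False
    protease_label: str | None = None

    @property
    def any(self) -> bool:
        return self.signal_transit_propeptide or self.dipeptidase or self.known_protease_site


def _make_aligner(gap_open: float = -9.5, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    # Biostrings convention: a gap of length L costs gapOpening + L*gapExtension,
    # so the first gapped residue costs open+extend here.
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


def locate_in_reference(
    proteoform_seq: str,
    reference_seq: str,
    reference_accession: str = "",
    identity_floor: float = 0.3,
    gap_open: float = -9.5,
    gap_extend: float = -0.5,
) -> AlignmentResult:
    """Place a proteoform on its reference protein.

    Exact substrings (including exact suffixes from an internal start and
    exact extension, where the reference is a suffix of the proteoform) skip
    alignment; everything else goes through the overlap aligner.  Identity
    below ``identity_floor`` over the aligned span means no reliable
    reference (mode "none").
    """
    if not proteoform_seq or not reference_seq:
        raise ValueError("sequences must be non-empty")

    # exact suffix first: an N-terminal truncation is a suffix of its
    # reference, and suffix placement is unambiguous even in low-complexity
    # sequence where find() would return an earlier occurrence
    if reference_seq.endswith(proteoform_seq):
        pos = len(reference_seq) - len(proteoform_seq)
        return AlignmentResult(
            "exact_substring", reference_accession,
            (pos + 1, len(reference_seq)), (1, len(proteoform_seq)),
            score=float(len(proteoform_seq)), identity=1.0,
            proteoform_seq=proteoform_seq, reference_seq=reference_seq,
        )
    pos = reference_seq.find(proteoform_seq)
    if pos >= 0:
        return AlignmentResult(
            "exact_substring", reference_accession,
            (pos + 1, pos + len(proteoform_seq)), (1, len(proteoform_seq)),
            score=float(len(proteoform_seq)), identity=1.0,
            proteoform_seq=proteoform_seq, reference_seq=reference_seq,
        )
    pos = proteoform_seq.find(reference_seq)
    if pos >= 0:
        # extension: the reference is contained in the proteoform
        return AlignmentResult(
            "exact_substring", reference_accession,
            (1, len(reference_seq)), (pos + 1, pos + len(reference_seq)),
            score=float(len(reference_seq)), identity=1.0,
            proteoform_seq=proteoform_seq, reference_seq=reference_seq,
        )

    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(reference_seq, proteoform_seq)[0]
    ref_blocks, query_blocks = alignment.aligned
    if len(ref_blocks) == 0:
        return AlignmentResult("none", reference_accession, (0, 0), (0, 0),
                               float(alignment.score), 0.0,
                               proteoform_seq, reference_seq)
    matches = 0
    aligned_len = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        aligned_len += re_ - rs
        for r, q in zip(reference_seq[rs:re_], proteoform_seq[qs:qe]):
            matches += r == q
    identity = matches / aligned_len if aligned_len else 0.0
    ref_span = (int(ref_blocks[0][0]) + 1, int(ref_blocks[-1][1]))
    query_span = (int(query_blocks[0][0]) + 1, int(query_blocks[-1][1]))
    mode = "overlap_alignment" if identity >= identity_floor else "none"
    return AlignmentResult(mode, reference_accession, ref_span, query_span,
                           float(alignment.score), identity,
                           proteoform_seq, reference_seq)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _scan_motifs(sequence: str, motif_table: dict[str, str]) -> list[str]:
    return sorted(
        label for label, pattern in motif_table.items() if re.search(pattern, sequence)
    )


def region_delta(
    alignment: AlignmentResult,
    feature_table: pd.DataFrame,
    motif_table: dict[str, str] | None = None,
) -> RegionDelta:
    """Lost/gained ranges of a placed proteoform, intersected with features.

    Features overlapping a lost reference range are reported with their
    overlap fraction (any overlap counts, with the fraction of the feature
    covered).  Lost and gained sequence stretches are scanned against the
    motif regex table.
    """
    if alignment.mode == "none":
        raise ValueError("cannot derive regions without a reliable reference")
    motif_table = BUILTIN_MOTIFS if motif_table is None else motif_table
    ref_len = len(alignment.reference_seq)
    pf_len = len(alignment.proteoform_seq)
    if len(feature_table) and (feature_table["end"] > ref_len).any():
        raise ValueError("feature ranges exceed reference length")

    delta = RegionDelta()
    ref_start = alignment.ref_span[0]
    query_start = alignment.query_span[0]
    if ref_start > 1:                      # truncation: N-terminal loss
        delta.lost.append((1, ref_start - 1))
    if query_start > 1:                    # extension: gained prefix
        delta.gained.append((1, query_start - 1))
        # features still spanning the reference N-terminus are displaced
        for _, feat in feature_table.iterrows():
            if feat["start"] <= 2:
                delta.lost_features.append((feat["label"], 0.0))

    for lost_range in delta.lost:
        for _, feat in feature_table.iterrows():
            frange = (int(feat["start"]), int(feat["end"]))
            ov = _overlap(lost_range, frange)
            if ov > 0:
                fraction = ov / (frange[1] - frange[0] + 1)
                delta.lost_features.append((feat["label"], fraction))

    lost_seq = "".join(
        alignment.reference_seq[s - 1: e] for s, e in delta.lost
    )
    gained_seq = "".join(
        alignment.proteoform_seq[s - 1: e] for s, e in delta.gained
    )
    if lost_seq:
        delta.lost_motifs = _scan_motifs(lost_seq, motif_table)
    if gained_seq:
        delta.gained_motifs = _scan_motifs(gained_seq, motif_table)
    return delta


def check_processing_origin(
    start: int,
    feature_table: pd.DataFrame,
    protease_sites: set[tuple[str, int]] | None = None,
    accession: str = "",
    margin: int = 1,
    dipeptidase_max_removed: int = 8,
) -> ProcessingFlags:
    """Could this truncation stem from proteolytic processing?

    Signal / transit / propeptide removal is flagged when the proteoform
    start falls within +/- ``margin`` residues of the mature N-terminus
    (feature end + 1).  Dipeptidase trimming is flagged for an even number of
    removed residues up to ``dipeptidase_max_removed``; a user-supplied
    (accession, start) protease-site table flags known cleavage sites.
    """
    if start < 1:
        raise ValueError("offset/start must be >= 1")
    flags = ProcessingFlags()
    maturation_features = feature_table[
        feature_table["feature_type"].isin(["signal", "transit", "propeptide"])
    ]
    for _, feat in maturation_features.iterrows():
        mature_start = int(feat["end"]) + 1
        if abs(start - mature_start) <= margin:
            flags.signal_transit_propeptide = True
            flags.processing_distance = start - mature_start
            break

    removed = start - 1
    if 0 < removed <= dipeptidase_max_removed and removed % 2 == 0:
        flags.dipeptidase = True

    if protease_sites and (accession, start) in protease_sites:
        flags.known_protease_site = True
        flags.protease_label = "user_table"
    return flags


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in kilodaltons (one decimal of kD precision
    is what reports use; full precision is returned).

    Average residue masses plus one water; unknown residue X contributes the
    mean residue mass; any other unknown residue raises.
    """
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for residue in sequence:
        try:
            total += AVERAGE_RESIDUE_MASS[residue]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r}") from None
    return total / 1000.0
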