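"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the downstream analysis
assumes: genes with canonical proteins plus truncated / 5'-extended N-terminal
proteoforms, protease-specific N-terminal peptides with in-vivo vs chemical
(heavy) acetylation, label-free interactome matrices with consistent
background proteins, spiked bait-specific preys and left-censored (MNAR)
missingness, and length-proportional spectral counts across tissues.

Randomness contract: one pseudo-random stream per operation, derived from the
master seed by a named substream label, so adding an operation never perturbs
another's draws.  A fixed seed gives bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PEPTIDE_COLUMNS, ProteomeDB, QuantMatrix

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# Rough human amino-acid background frequencies.
AA_FREQ = np.array([
    0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
    0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
])
AA_FREQ = AA_FREQ / AA_FREQ.sum()

PROTEASE_RULES = {
    "trypsin": ("KR", "P"),      # after K/R, not before P
    "chymotrypsin": ("FWYL", ""),
    "gluc": ("E", ""),
}


@dataclass
class ProteoformTruth:
    gene: str
    canonical_accession: str
    accession: str           # accession the proteoform's peptides map to
    offset: int              # start on canonical; negative = extension length
    start_codon_class: str   # "AUG" or "near-cognate"
    acetylation_fraction: float
    source_class: str        # canonical / isoform / riboseq


@dataclass
class SimTruth:
    proteoforms: list[ProteoformTruth] = field(default_factory=list)
    interaction_truth: list[tuple] = field(default_factory=list)  # (bait, prey, effect)
    tissue_truth: list[tuple] = field(default_factory=list)       # (acc, tissue, mult)


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(AA20, size=length - 1, p=AA_FREQ)
    return "M" + "".join(body)


def generate_proteome(
    n_genes: int = 200,
    proteoform_rate: float = 0.3,
    extension_rate: float = 0.06,
    length_range: tuple[int, int] = (50, 2000),
    signal_fraction: float = 0.1,
    domain_rate: float = 0.8,
    seed: int = 0,
) -> tuple[ProteomeDB, pd.DataFrame, SimTruth]:
    """Generate a proteome with truncated / extended proteoforms and features.

    Each gene gets one canonical entry.  With probability ``proteoform_rate``
    the gene additionally expresses an internal-start proteoform (truncation
    start uniform over [5, 0.9*L]); with probability ``extension_rate`` a
    5'-extended proteoform (5-60 prepended residues) recorded as a separate
    isoform/riboseq database entry.  Domain and signal-peptide features are
    placed without overlap.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not (0 <= proteoform_rate <= 1 and 0 <= extension_rate <= 1):
        raise ValueError("rates must be within [0, 1]")
    lo, hi = length_range
    if lo < 50 or hi > 2000 or lo > hi:
        raise ValueError("length_range must be within [50, 2000]")

    rng = _rng(seed, "generate_proteome")
    db = ProteomeDB()
    truth = SimTruth()
    feature_rows: list[dict] = []

    for i in range(n_genes):
        gene = f"GENE{i + 1:04d}"
        acc = f"P{i + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_protein(rng, length)
        db.add(acc, seq, "canonical", gene)
        truth.proteoforms.append(
            ProteoformTruth(gene, acc, acc, 1, "AUG", float(rng.uniform(0.6, 1.0)), "canonical")
        )

        # non-overlapping features: optional signal peptide then domains
        cursor = 1
        if rng.random() < signal_fraction:
            sig_end = int(rng.integers(15, 31))
            feature_rows.append(
                {"accession": acc, "feature_type": "signal", "start": 1,
                 "end": sig_end, "label": "signal peptide"}
            )
            cursor = sig_end + 1
        n_domains = int(rng.poisson(domain_rate))
        for d in range(n_domains):
            if cursor + 20 >= length:
                break
            dstart = int(rng.integers(cursor, min(cursor + 80, length - 20)))
            dend = int(rng.integers(dstart + 10, min(dstart + 120, length) + 1))
            feature_rows.append(
                {"accession": acc, "feature_type": "domain", "start": dstart,
                 "end": dend, "label": f"domain_{d + 1}"}
            )
            cursor = dend + 1

        if rng.random() < proteoform_rate:
            start = int(rng.integers(5, max(6, int(0.9 * length)) + 1))
            codon = "AUG" if seq[start - 1] == "M" or rng.random() < 0.5 else "near-cognate"
            truth.proteoforms.append(
                ProteoformTruth(gene, acc, acc, start, codon,
                                float(rng.uniform(0.0, 1.0)), "canonical")
            )
        if rng.random() < extension_rate:
            ext_len = int(rng.integers(5, 61))
            ext_seq = "M" + "".join(rng.choice(AA20, size=ext_len - 1, p=AA_FREQ)) + seq
            if rng.random() < 0.5:
                ext_acc, source = f"{acc}-2", "isoform"
            else:
                ext_acc, source = f"ENST{i + 1:08d}", "riboseq"
            db.add(ext_acc, ext_seq, source, gene)
            truth.proteoforms.append(
                ProteoformTruth(gene, acc, ext_acc, -ext_len, "near-cognate",
                                float(rng.uniform(0.0, 1.0)), source)
            )

    features = pd.DataFrame(
        feature_rows, columns=["accession", "feature_type", "start", "end", "label"]
    )
    return db, features, truth


def _nterm_peptide(seq: str, start: int, protease: str) -> str | None:
    """N-terminal peptide of the proteoform starting at ``start`` (1-based)."""
    residues, no_before = PROTEASE_RULES[protease]
    for i in range(start - 1, len(seq) - 1):
        if seq[i] in residues and (not no_before or seq[i + 1] not in no_before):
            pep = seq[start - 1: i + 1]
            return pep
    return None


def _internal_peptide(
    seq: str, protease: str, rng: np.random.Generator
) -> tuple[str, int] | None:
    """A fully cleaved internal peptide (no translational start)."""
    residues, no_before = PROTEASE_RULES[protease]
    sites = [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in residues and (not no_before or seq[i + 1] not in no_before)
    ]
    starts = [s + 1 for s in sites if s + 1 > 2]
    if not starts:
        return None
    start = int(rng.choice(starts))
    pep = _nterm_peptide(seq, start, protease)
    if pep is None:
        return None
    return pep, start


def digest_nterm(
    proteome: ProteomeDB,
    truth: SimTruth,
    proteases: tuple[str, ...] = ("trypsin", "chymotrypsin", "gluc"),
    acetylation_model=None,
    contamination_rate: float = 0.0,
    min_length: int = 4,
    max_length: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Digest every expressed proteoform with each protease and emit the
    observed N-terminal peptides as a PeptideTable.

    Per observation the modification state is sampled: in-vivo Nt-acetyl with
    the probability given by ``acetylation_model`` (default: the truth
    proteoform's acetylation fraction), otherwise heavy (chemical) acetyl
    marking a free in-vivo N-terminus.  Internal "contaminant" peptides with
    no translational start are injected at ``contamination_rate`` (extra rows
    per real peptide) to exercise the downstream filters.  Spectral counts
    follow a shifted Poisson (>= 1).
    """
    if not proteases:
        raise ValueError("empty protease set")
    unknown = set(proteases) - set(PROTEASE_RULES)
    if unknown:
        raise ValueError(f"unknown proteases {sorted(unknown)}")
    rng = _rng(seed, "digest_nterm")
    if acetylation_model is None:
        acetylation_model = lambda pf: pf.acetylation_fraction  # noqa: E731

    rows: list[dict] = []
    n_real = 0
    for pf in truth.proteoforms:
        entry = proteome[pf.accession]
        start = 1 if pf.offset < 0 else pf.offset
        for protease in proteases:
            pep = _nterm_peptide(entry.sequence, start, protease)
            if pep is None or not (min_length <= len(pep) <= max_length):
                continue
            n_psm = 1 + int(rng.poisson(2.0))
            p_acet = float(acetylation_model(pf))
            k = int(rng.binomial(n_psm, p_acet))
            frac = k / n_psm
            mod = "acetyl_in_vivo" if k > 0 else "acetyl_heavy"
            rows.append({
                "sequence": pep,
                "accessions": pf.accession,
                "start": start,
                "nterm_mod": mod,
                "protease": protease,
                "spectral_count": n_psm,
                "acetylation_fraction": frac,
                "riboseq_support": bool(pf.source_class == "riboseq"
                                        or rng.random() < 0.3),
                "start_codon": pf.start_codon_class,
                "in_5utr": pf.offset < 0,
                "riboseq_region": ("utr5" if pf.offset < 0 else "cds")
                if pf.source_class == "riboseq" else "n/a",
            })
            n_real += 1

    n_contaminants = int(rng.binomial(n_real, contamination_rate)) if n_real else 0
    accs = proteome.accessions()
    made = 0
    while made < n_contaminants:
        acc = accs[int(rng.integers(len(accs)))]
        protease = proteases[int(rng.integers(len(proteases)))]
        got = _internal_peptide(proteome[acc].sequence, protease, rng)
        if got is None:
            continue
        pep, start = got
        if not (min_length <= len(pep) <= max_length):
            continue
        rows.append({
            "sequence": pep,
            "accessions": acc,
            "start": start,
            "nterm_mod": "none",
            "protease": protease,
            "spectral_count": 1 + int(rng.poisson(0.5)),
            "acetylation_fraction": 0.0,
            "riboseq_support": False,
            "start_codon": "unknown",
            "in_5utr": False,
            "riboseq_region": "n/a",
        })
        made += 1

    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


@dataclass
class MissingModel:
    """Left-censored (MNAR) missingness: P(missing | x) = logistic(steepness *
    (limit - x)), plus a completely-at-random component."""

    limit: float | None = None   # None -> 5th percentile of generated values
    steepness: float = 2.0
    mcar_rate: float = 0.0


def simulate_interactome_matrix(
    baits: list[str],
    control: str = "eDHFR",
    n_replicates: int = 3,
    n_background: int = 400,
    truth_edges: list[tuple[str, str, float]] | None = None,
    baseline_sd: float = 0.3,
    bait_offsets: dict[str, float] | None = None,
    missing_model: MissingModel | None = None,
    background_mean: float = 25.0,
    background_spread: float = 2.0,
    bait_level: float = 30.0,
    seed: int = 0,
) -> tuple[QuantMatrix, SimTruth]:
    """Simulate a Virotrap/AP-MS style label-free matrix.

    Background proteins share one mean log2 intensity across all baits
    (replicate noise sd = ``baseline_sd``); truth preys get their log2 effect
    added in their bait's samples; bait rows are present only in their own
    samples at ``bait_level`` plus the per-bait offset (to exercise the
    bait-level correction).  Values are censored by ``missing_model``.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if control not in baits:
        baits = [control] + list(baits)
    truth_edges = list(truth_edges or [])
    bait_offsets = dict(bait_offsets or {})
    missing_model = missing_model or MissingModel()
    rng = _rng(seed, "simulate_interactome_matrix")

    samples, groups = [], {}
    for bait in baits:
        for rep in range(1, n_replicates + 1):
            name = f"{bait}_r{rep}"
            samples.append(name)
            groups[name] = bait

    prey_names = sorted({prey for _, prey, _ in truth_edges})
    background = [f"BG{i + 1:05d}" for i in range(n_background)]
    proteins = background + prey_names + [f"BAIT_{b}" for b in baits]

    n_bg_like = n_background + len(prey_names)
    base = rng.normal(background_mean, background_spread, size=n_bg_like)
    values = np.full((len(proteins), len(samples)), np.nan)
    noise = rng.normal(0.0, baseline_sd, size=(n_bg_like, len(samples)))
    values[:n_bg_like, :] = base[:, None] + noise

    effect_of = {(bait, prey): eff for bait, prey, eff in truth_edges}
    for j, sample in enumerate(samples):
        bait = groups[sample]
        for k, prey in enumerate(prey_names):
            eff = effect_of.get((bait, prey))
            if eff is not None:
                values[n_background + k, j] += eff
    for b, bait in enumerate(baits):
        row = n_bg_like + b
        for j, sample in enumerate(samples):
            if groups[sample] == bait:
                values[row, j] = (bait_level + bait_offsets.get(bait, 0.0)
                                  + rng.normal(0.0, baseline_sd))

    # left-censoring on non-bait rows; bait rows stay near-complete by design
    observed = values[:n_bg_like, :]
    limit = (np.nanpercentile(observed, 5.0)
             if missing_model.limit is None else missing_model.limit)
    if np.isfinite(limit):
        p_mnar = 1.0 / (1.0 + np.exp(-missing_model.steepness * (limit - observed)))
    else:
        p_mnar = np.zeros_like(observed)
    drop = rng.random(observed.shape) < p_mnar
    if missing_model.mcar_rate > 0:
        drop |= rng.random(observed.shape) < missing_model.mcar_rate
    values[:n_bg_like, :][drop] = np.nan

    df = pd.DataFrame(values, index=proteins, columns=samples)
    genes = pd.Series(
        {p: (p.replace("BAIT_", "") if p.startswith("BAIT_") else p) for p in proteins}
    )
    flags = pd.DataFrame(
        False, index=df.index,
        columns=["reverse", "contaminant", "only_identified_by_site"],
    )
    truth = SimTruth(interaction_truth=truth_edges)
    return QuantMatrix(df, genes, flags, pd.Series(groups), "lfq"), truth


def simulate_tissue_counts(
    lengths: dict[str, int],
    tissues: list[str],
    n_replicates: int = 3,
    multipliers: dict[tuple[str, str], float] | None = None,
    depth: float = 0.1,
    seed: int = 0,
) -> QuantMatrix:
    """Spectral counts ~ Poisson(multiplier * length * depth) per replicate.

    The length proportionality is built in so the NSAF length correction is
    testable; tissue-specific proteoforms get multiplier 0 outside their
    tissues, producing all-zero counts there.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    multipliers = multipliers or {}
    rng = _rng(seed, "simulate_tissue_counts")
    proteins = list(lengths)
    samples, groups = [], {}
    for tissue in tissues:
        for rep in range(1, n_replicates + 1):
            name = f"{tissue}_r{rep}"
            samples.append(name)
            groups[name] = tissue
    counts = np.zeros((len(proteins), len(samples)), dtype=float)
    for i, acc in enumerate(proteins):
        for j, sample in enumerate(samples):
            mult = multipliers.get((acc, groups[sample]), 1.0)
            rate = mult * lengths[acc] * depth
            counts[i, j] = rng.poisson(rate) if rate > 0 else 0.0
    df = pd.DataFrame(counts, index=proteins, columns=samples)
    genes = pd.Series({p: p for p in proteins})
    flags = pd.DataFrame(
        False, index=df.index,
        columns=["reverse", "contaminant", "only_identified_by_site"],
    )
    return QuantMatrix(df, genes, flags, pd.Series(groups), "spectral_count")


def catalog_records_from_counts(
    counts: dict[tuple[str, str, str, str], int],
):
    """Build classified catalogue records with prescribed taxonomy counts.

    ``counts`` maps (source_class, start_class, confidence, riboseq_region)
    -> number of records; useful for reproducing printed taxonomy tables.
    """
    from .catalog import ProteoformRecord

    records = []
    i = 0
    for (source, start_class, confidence, region), n in counts.items():
        for _ in range(n):
            i += 1
            records.append(ProteoformRecord(
                accession=f"FX{i:06d}",
                gene=f"GFX{i:06d}",
                source_class=source,
                start_class=start_class,
                riboseq_region=region,
                confidence=confidence,
                start=1 if start_class == "database_annotated" else 50,
                offset_vs_canonical=0 if start_class == "database_annotated" else 49,
            ))
    return records


def simulate_filter_fixture(
    n_identified: int = 2134,
    n_flagged: int = 137,
    n_pass: int = 842,
    baits: tuple[str, ...] = ("eDHFR", "CSDE1_FL", "CSDE1_PR", "MAVS_FL",
                              "MAVS_PR", "TSC22D3_FL", "TSC22D3_PR"),
    n_replicates: int = 3,
    min_valid: int = 3,
    seed: int = 0,
) -> QuantMatrix:
    """A matrix built to a given experimental set's dimensions.

    Of ``n_identified`` proteins, ``n_flagged`` carry contaminant / reverse /
    identified-by-site flags; of the remainder, exactly ``n_pass`` have at
    least ``min_valid`` valid values in at least one group and the rest have
    at most ``min_valid - 1`` valid values in every group.
    """
    if n_flagged + n_pass > n_identified:
        raise ValueError("n_flagged + n_pass must not exceed n_identified")
    rng = _rng(seed, "simulate_filter_fixture")
    samples, groups = [], {}
    for bait in baits:
        for rep in range(1, n_replicates + 1):
            name = f"{bait}_r{rep}"
            samples.append(name)
            groups[name] = bait
    n_samples = len(samples)
    proteins = [f"PG{i + 1:05d}" for i in range(n_identified)]
    values = np.full((n_identified, n_samples), np.nan)
    group_cols: dict[str, list[int]] = {}
    for j, s in enumerate(samples):
        group_cols.setdefault(groups[s], []).append(j)

    base = rng.normal(25.0, 2.0, size=n_identified)
    is_flagged = np.zeros(n_identified, dtype=bool)
    is_flagged[:n_flagged] = True
    is_pass = np.zeros(n_identified, dtype=bool)
    is_pass[n_flagged: n_flagged + n_pass] = True
    for i in range(n_identified):
        if is_flagged[i] or is_pass[i]:
            # at least one complete group; other groups present at random
            complete = {rng.choice(list(group_cols))}
            for g, cols in group_cols.items():
                if g in complete or rng.random() < 0.7:
                    for j in cols:
                        values[i, j] = base[i] + rng.normal(0, 0.3)
        else:
            # at most min_valid - 1 valid values in every group
            for g, cols in group_cols.items():
                k = int(rng.integers(0, min_valid))
                for j in rng.choice(cols, size=k, replace=False):
                    values[i, j] = base[i] + rng.normal(0, 0.3)

    order = rng.permutation(n_identified)
    values = values[order]
    is_flagged = is_flagged[order]
    df = pd.DataFrame(values, index=proteins, columns=samples)
    flags = pd.DataFrame(
        False, index=df.index,
        columns=["reverse", "contaminant", "only_identified_by_site"],
    )
    kinds = rng.integers(0, 3, size=n_identified)
    for i in range(n_identified):
        if is_flagged[i]:
            flags.iloc[i, int(kinds[i])] = True
    genes = pd.Series({p: p for p in proteins})
    return QuantMatrix(df, genes, flags, pd.Series(groups), "lfq")
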