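"""Tissue-expression analysis of proteoforms from spectral counts.

PSM-level identifications are filtered (decoys, contaminants, q-value),
aggregated to unique peptides and proteoform tables per sample, and
quantified by the normalized spectral abundance factor: SAF = spectral count
/ protein length, NSAF = SAF / sum of SAFs in the sample (a per-sample
simplex, correcting the length bias of spectral counting).  Non-canonical
proteoforms are quantified only from peptides that do not map to any
canonical protein.  Differential expression across tissues uses a
per-proteoform one-way linear model on log2 NSAF with empirical-Bayes
moderated variances (per-protein variances shrunk toward a pooled prior with
moment-matched prior degrees of freedom) and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ProteomeDB
from .catalog import sort_accessions


@dataclass
class NsafMatrix:
    nsaf: pd.DataFrame          # proteoforms x samples, rows on the simplex
    log2_nsaf: pd.DataFrame     # log2 of positive entries, NaN elsewhere
    spectral_counts: pd.DataFrame
    groups: pd.Series           # sample -> tissue


def aggregate_psms(
    psms: pd.DataFrame,
    proteome: ProteomeDB,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Aggregate a PSM table to proteoform counts per sample and replicate.

    Decoy and contaminant hits are removed and PSMs kept at q <=
    ``q_threshold``.  Accession lists are sorted (canonical, isoform,
    Ribo-seq; then higher whole-sample peptide count, smallest start,
    alphabetical accession) and the first becomes the primary accession.
    PSMs are grouped by peptide — N-terminally acetylated, then
    highest-scoring PSM wins — then peptides by primary accession, yielding
    unique-peptide and spectral counts per proteoform per sample/replicate.
    """
    df = psms.copy()
    n_in = len(df)
    df = df[~df["decoy"].astype(bool) & ~df["contaminant"].astype(bool)]
    df = df[df["q_value"] <= q_threshold]
    unknown = {
        acc for accs in df["accessions"] for acc in str(accs).split(";")
    } - set(proteome.accessions())
    if unknown:
        raise ValueError(f"PSMs reference unknown accessions {sorted(unknown)[:5]}")

    out_rows = []
    for sample, sample_df in df.groupby("sample"):
        # whole-sample peptide count per accession for the sorting priority
        pep_acc = sample_df[["sequence", "accessions"]].drop_duplicates()
        counts: dict[str, int] = {}
        starts: dict[str, int] = {}
        for _, row in pep_acc.iterrows():
            for acc in str(row["accessions"]).split(";"):
                counts[acc] = counts.get(acc, 0) + 1
                pos = proteome[acc].sequence.find(row["sequence"])
                if pos >= 0:
                    start = pos + 1
                    starts[acc] = min(starts.get(acc, start), start)
        sample_df = sample_df.copy()
        sample_df["primary_accession"] = [
            sort_accessions(str(a).split(";"), proteome, counts, starts)[0]
            for a in sample_df["accessions"]
        ]
        for replicate, rep_df in sample_df.groupby("replicate"):
            # best PSM per peptide: acetylated first, then highest score
            rep_df = rep_df.sort_values(
                ["nterm_acetylated", "psm_score"], ascending=[False, False],
                kind="stable",
            )
            spectral = rep_df.groupby("sequence").size()
            best = rep_df.drop_duplicates("sequence").set_index("sequence")
            best["spectral_count"] = spectral
            for acc, acc_df in best.groupby("primary_accession"):
                out_rows.append({
                    "accession": acc,
                    "sample": sample,
                    "replicate": replicate,
                    "unique_peptides": len(acc_df),
                    "spectral_count": int(acc_df["spectral_count"].sum()),
                    "peptides": ";".join(sorted(acc_df.index)),
                })
    result = pd.DataFrame(out_rows)
    dropped = n_in - len(df)
    import logging

    logging.getLogger("pfp").info(
        "aggregate_psms: %d PSMs in, %d retained (%d dropped)", n_in, len(df), dropped
    )
    return result


def restrict_noncanonical(
    protein_table: pd.DataFrame,
    proteome: ProteomeDB,
) -> pd.DataFrame:
    """Drop canonical-mappable peptides from non-canonical proteoform counts.

    For proteoforms whose primary accession is not canonical, any peptide
    occurring as a substring of a canonical protein is excluded; counts are
    recomputed from the surviving peptides (proteoforms left with none lose
    their quantification in that sample).
    """
    canon = "\x00".join(proteome.canonical_sequences())
    rows = []
    for _, row in protein_table.iterrows():
        acc = row["accession"]
        if proteome[acc].source_class == "canonical":
            rows.append(row)
            continue
        peptides = [p for p in str(row["peptides"]).split(";") if p]
        kept = [p for p in peptides if p not in canon]
        if not kept:
            continue
        new = row.copy()
        scale = row["spectral_count"] / max(len(peptides), 1)
        new["unique_peptides"] = len(kept)
        new["spectral_count"] = int(round(scale * len(kept)))
        new["peptides"] = ";".join(kept)
        rows.append(new)
    return pd.DataFrame(rows).reset_index(drop=True)


def compute_nsaf(
    counts: pd.DataFrame,
    lengths: pd.Series | dict,
    groups: pd.Series | None = None,
) -> NsafMatrix:
    """NSAF from spectral counts: SAF = SpC/length, normalized per sample.

    Zero-count proteoforms become missing (NaN), not -inf, in the log2
    matrix; a sample with no counts at all cannot be normalized and raises.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"no length for {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("protein lengths must be positive")
    saf = counts.div(lengths, axis=0)
    totals = saf.sum(axis=0)
    if (totals == 0).any():
        dead = totals.index[totals == 0].tolist()
        raise ValueError(f"all-zero sample(s) {dead[:5]}: cannot normalize")
    nsaf = saf.div(totals, axis=1)
    log2 = np.log2(nsaf.mask(nsaf <= 0))
    if groups is None:
        groups = pd.Series({s: s for s in counts.columns})
    return NsafMatrix(nsaf, log2, counts.copy(), groups)


def _fit_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Works on z = log(s2): E[z] and Var[z] under the scaled-F model give the
    prior df (by inverting the trigamma function) and the prior variance.
    Returns (prior_df, prior_s2); prior_df is inf for degenerate spread.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        return np.inf, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    # invert trigamma(d0/2) = e_var by Newton iteration
    x = 0.5 + 1.0 / e_var
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / e_var) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10:
            break
    d0 = 2.0 * x
    s0 = np.exp(e_mean + special.digamma(x) - np.log(x))
    return float(d0), float(s0)


def differential_tissue(
    log2_nsaf: pd.DataFrame,
    groups: pd.Series,
    prior_df: float | None = None,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Moderated one-way differential expression across tissues.

    Proteoforms are retained iff observed in all replicates of at least one
    tissue; per proteoform a fixed-effects tissue model is fit on the
    observed values, per-protein variances are shrunk toward the pooled
    prior (``prior_df`` None -> estimated by moment matching; 0 -> ordinary
    least squares), and the tissue F test plus all pairwise tissue contrasts
    are reported with Benjamini-Hochberg adjusted p-values.

    Returns ``(per-proteoform table, per-contrast long table)``.
    """
    tissues = sorted(groups.unique())
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    samples = [s for s in log2_nsaf.columns]
    group_of = groups.reindex(samples)
    cols_by_tissue = {t: [s for s in samples if group_of[s] == t] for t in tissues}
    if any(len(c) < 2 for c in cols_by_tissue.values()):
        raise ValueError("need >= 2 replicates per tissue")

    X = log2_nsaf[samples].to_numpy(dtype=float)
    observed = np.isfinite(X)
    # completeness filter: all replicates of at least one tissue
    complete_any = np.zeros(X.shape[0], dtype=bool)
    for t in tissues:
        idx = [samples.index(s) for s in cols_by_tissue[t]]
        complete_any |= observed[:, idx].all(axis=1)
    keep = complete_any
    X = X[keep]
    observed = observed[keep]
    index = log2_nsaf.index[keep]

    n_prot = X.shape[0]
    k = len(tissues)
    counts = np.zeros((n_prot, k))
    sums = np.zeros((n_prot, k))
    sumsq = np.zeros((n_prot, k))
    for j, t in enumerate(tissues):
        idx = [samples.index(s) for s in cols_by_tissue[t]]
        block = X[:, idx]
        obs = observed[:, idx]
        counts[:, j] = obs.sum(axis=1)
        sums[:, j] = np.where(obs, block, 0.0).sum(axis=1)
        sumsq[:, j] = np.where(obs, block**2, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    n_total = counts.sum(axis=1)
    grand = sums.sum(axis=1) / n_total
    present = counts > 0
    k_eff = present.sum(axis=1)
    ss_within = (sumsq.sum(axis=1)
                 - np.nansum(counts * np.where(present, means, 0.0) ** 2, axis=1))
    ss_between = np.nansum(
        counts * (np.where(present, means, grand[:, None]) - grand[:, None]) ** 2,
        axis=1,
    )
    df_between = k_eff - 1.0
    df_within = n_total - k_eff
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ss_within / df_within
    s2 = np.where(df_within > 0, s2, np.nan)

    if prior_df is None:
        d0, s0 = _fit_prior(s2, df_within)
    elif prior_df == 0:
        d0, s0 = 0.0, 1.0
    else:
        d0 = float(prior_df)
        finite = np.isfinite(s2)
        s0 = float(np.median(s2[finite])) if finite.any() else 1.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0 + df_within * np.where(np.isfinite(s2), s2, 0.0)) / (
            d0 + df_within
        )
        s2_post = np.where(df_within > 0, s2_post, np.nan)
        df_total = d0 + df_within

    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat = (ss_between / df_between) / s2_post
    valid = (df_between >= 1) & np.isfinite(f_stat) & (s2_post > 0)
    p_f = np.full(n_prot, np.nan)
    p_f[valid] = stats.f.sf(
        f_stat[valid], df_between[valid],
        np.where(np.isinf(df_total[valid]), 1e9, df_total[valid]),
    )
    adj = np.full(n_prot, np.nan)
    if valid.any():
        adj[valid] = multipletests(p_f[valid], method="fdr_bh")[1]

    result = pd.DataFrame({
        "F": f_stat,
        "p_value": p_f,
        "adj_p_value": adj,
        "significant": adj <= fdr_threshold,
        "df_between": df_between,
        "df_within": df_within,
        "s2": s2,
        "s2_posterior": s2_post,
    }, index=index)
    result.attrs["prior_df"] = d0
    result.attrs["prior_s2"] = s0

    contrast_rows = []
    for a, b in combinations(range(k), 2):
        ok = (counts[:, a] > 0) & (counts[:, b] > 0) & np.isfinite(s2_post)
        with np.errstate(invalid="ignore", divide="ignore"):
            est = means[:, a] - means[:, b]
            se = np.sqrt(s2_post * (1.0 / counts[:, a] + 1.0 / counts[:, b]))
            t_stat = est / se
        dfree = np.where(np.isinf(df_total), 1e9, df_total)
        p_t = 2.0 * stats.t.sf(np.abs(t_stat), dfree)
        for i in np.where(ok)[0]:
            contrast_rows.append({
                "proteoform": index[i],
                "contrast": f"{tissues[a]} vs {tissues[b]}",
                "estimate": est[i],
                "t": t_stat[i],
                "p_value": p_t[i],
            })
    contrasts = pd.DataFrame(
        contrast_rows,
        columns=["proteoform", "contrast", "estimate", "t", "p_value"],
    )
    if len(contrasts):
        contrasts["adj_p_value"] = multipletests(
            contrasts["p_value"], method="fdr_bh"
        )[1]
        contrasts["significant"] = contrasts["adj_p_value"] <= fdr_threshold
    return result, contrasts
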