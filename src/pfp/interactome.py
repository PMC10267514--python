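"""Differential interactome statistics for multi-bait label-free designs.

The engine mirrors the standard Virotrap/AP-MS workflow: remove contaminant /
reverse / identified-by-site rows, log2-transform, keep proteins with at
least three valid values in one bait group, impute left-censored missing
values (QRILC-like truncated-normal or down-shifted normal), fit a one-way
fixed-effects model per protein (response = mu + bait + error) with an
overall F test and pairwise t contrasts, control the FDR (Benjamini-Hochberg
or a uniform-Beta mixture fit by EM), call candidate interactors against the
control bait, and apply the bait-corrected proteoform-contrast double filter
for full-length (FL) vs N-terminal proteoform (PR) comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import QuantMatrix

logger = logging.getLogger("pfp")


@dataclass
class DesignSet:
    """Sample layout of one experimental set: baits, replicates, control."""

    samples: list[tuple[str, str, int]]   # (sample id, bait label, replicate)
    control_bait: str
    bait_pairs: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def __post_init__(self):
        baits = {b for _, b, _ in self.samples}
        if self.control_bait not in baits:
            raise ValueError(f"control bait {self.control_bait!r} has no samples")

    @property
    def groups(self) -> pd.Series:
        return pd.Series({s: b for s, b, _ in self.samples})

    def replicates_of(self, bait: str) -> int:
        return sum(1 for _, b, _ in self.samples if b == bait)


def preprocess(
    matrix: QuantMatrix,
    min_valid: int = 3,
    log2_transform: bool = True,
) -> QuantMatrix:
    """Flag removal, log2 transform and the valid-value filter.

    Proteins with fewer than ``min_valid`` quantified values in every bait
    group are removed; in/out counts are logged so filter survivorship is
    auditable.
    """
    n_in = matrix.values.shape[0]
    flagged = matrix.flags.any(axis=1)
    values = matrix.values.loc[~flagged].copy()
    n_unflagged = values.shape[0]
    if log2_transform:
        values = np.log2(values.mask(values <= 0))
    group_of = matrix.groups
    keep = pd.Series(False, index=values.index)
    for bait in group_of.unique():
        cols = [s for s in values.columns if group_of[s] == bait]
        keep |= values[cols].notna().sum(axis=1) >= min_valid
    out = values.loc[keep]
    logger.info(
        "preprocess: %d proteins in, %d after flag removal, %d after >=%d-valid filter",
        n_in, n_unflagged, out.shape[0], min_valid,
    )
    if out.shape[0] == 0:
        logger.warning("preprocess: no protein passes the valid-value filter")
    return QuantMatrix(
        out,
        matrix.genes.reindex(out.index),
        matrix.flags.reindex(out.index),
        matrix.groups,
        matrix.value_kind,
    )


def impute(
    values: pd.DataFrame,
    method: str = "qrilc_like",
    shift: float = 1.8,
    spread: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Impute left-censored missing values in a log2 matrix.

    ``qrilc_like``: per sample, regress the observed order statistics on
    their censoring-aware standard-normal quantiles to recover the complete
    distribution's mean and sd, then draw imputations from the truncated
    lower tail.  ``shifted_normal``: per sample, draw from
    N(mean - shift*sd, (spread*sd)^2).  Columns with fewer than 5 observed
    values fall back to shifted_normal with a warning.  Seeded and
    reproducible; complete matrices are returned unchanged.
    """
    if method not in ("qrilc_like", "shifted_normal"):
        raise ValueError(f"unknown imputation method {method!r}")
    if not values.isna().any().any():
        return values.copy()
    rng = np.random.default_rng(seed)
    out = values.copy()
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        missing = ~np.isfinite(x)
        n_miss = int(missing.sum())
        if n_miss == 0:
            continue
        obs = x[~missing]
        if len(obs) == 0:
            # empty column: fall back to the matrix-wide distribution
            obs = values.to_numpy(dtype=float)
            obs = obs[np.isfinite(obs)]
        col_method = method
        if method == "qrilc_like" and len(obs) < 5:
            logger.warning(
                "impute: column %s has %d observed values; falling back to "
                "shifted_normal", col, len(obs),
            )
            col_method = "shifted_normal"
        mean, sd = float(np.mean(obs)), float(np.std(obs, ddof=1)) if len(obs) > 1 else 1.0
        if col_method == "shifted_normal":
            draws = rng.normal(mean - shift * sd, spread * sd, size=n_miss)
        else:
            n_total = len(x)
            frac_missing = n_miss / n_total
            order = np.sort(obs)
            # theoretical quantiles of the observed (uncensored upper) part
            ranks = (n_miss + np.arange(1, len(order) + 1) - 0.5) / n_total
            z = stats.norm.ppf(ranks)
            # robust fit on the upper portion, least affected by censoring
            upper = z >= np.quantile(z, 0.25)
            slope, intercept = np.polyfit(z[upper], order[upper], 1)
            mu_hat, sd_hat = float(intercept), abs(float(slope))
            if sd_hat <= 0:
                sd_hat = max(sd, 1e-6)
            cut = stats.norm.ppf(max(frac_missing, 1e-3))
            draws = mu_hat + sd_hat * stats.truncnorm.rvs(
                -np.inf, cut, size=n_miss, random_state=rng
            )
        x[missing] = draws
        out[col] = x
    return out


def fit_and_contrast(
    values: pd.DataFrame,
    groups: pd.Series,
    contrasts: list[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein one-way fixed-effects fit over bait labels.

    The bait effect is tested by an overall F test; each requested pairwise
    contrast by a t test with the pooled residual variance.  Estimates are
    group-mean differences; a positive estimate means enrichment in the
    first-named group of the contrast.

    Returns ``(anova table, contrast long table)``.
    """
    baits = sorted(groups.unique())
    for a, b in contrasts:
        if a not in baits or b not in baits:
            raise ValueError(f"contrast ({a!r}, {b!r}) names an absent bait")
    samples = list(values.columns)
    group_of = groups.reindex(samples)
    cols = {b: [j for j, s in enumerate(samples) if group_of[s] == b] for b in baits}
    X = values.to_numpy(dtype=float)
    n_prot, n_samples = X.shape
    k = len(baits)
    n_g = np.array([len(cols[b]) for b in baits], dtype=float)
    means = np.column_stack([X[:, cols[b]].mean(axis=1) for b in baits])
    grand = X.mean(axis=1)
    ss_between = ((means - grand[:, None]) ** 2 * n_g[None, :]).sum(axis=1)
    ss_total = ((X - grand[:, None]) ** 2).sum(axis=1)
    ss_within = ss_total - ss_between
    df_between = k - 1
    df_within = n_samples - k
    if df_within < 1:
        raise ValueError("design leaves no residual degrees of freedom")
    s2 = ss_within / df_within
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat = (ss_between / df_between) / s2
    p_f = stats.f.sf(f_stat, df_between, df_within)
    anova = pd.DataFrame({
        "F": f_stat,
        "p_value": p_f,
        "df_between": df_between,
        "df_within": df_within,
        "s2": s2,
    }, index=values.index)

    rows = []
    for a, b in contrasts:
        ia, ib = baits.index(a), baits.index(b)
        est = means[:, ia] - means[:, ib]
        se = np.sqrt(s2 * (1.0 / n_g[ia] + 1.0 / n_g[ib]))
        with np.errstate(invalid="ignore", divide="ignore"):
            t_stat = est / se
        p_t = 2.0 * stats.t.sf(np.abs(t_stat), df_within)
        frame = pd.DataFrame({
            "protein": values.index,
            "contrast": f"{a} vs {b}",
            "group_a": a,
            "group_b": b,
            "estimate": est,
            "t": t_stat,
            "p_value": p_t,
        })
        rows.append(frame)
    contrast_table = pd.concat(rows, ignore_index=True)
    return anova, contrast_table


def estimate_fdr(p_values, method: str = "bh") -> np.ndarray:
    """Convert p-values to q-values.

    ``bh``: Benjamini-Hochberg step-up.  ``mixture``: fit pi0*Uniform +
    (1-pi0)*Beta(a, 1) by EM and report q(p) = pi0*p / F_hat(p), forced
    monotone non-decreasing in p.  Both return values aligned with the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method != "mixture":
        raise ValueError(f"unknown FDR method {method!r}")

    eps = 1e-12
    pc = np.clip(p, eps, 1.0)
    pi0, a = 0.8, 0.3
    for _ in range(200):
        beta_dens = a * pc ** (a - 1.0)
        denom = pi0 + (1.0 - pi0) * beta_dens
        w = pi0 / denom                       # posterior P(null | p)
        pi0_new = float(np.mean(w))
        wa = 1.0 - w
        denom_a = -np.sum(wa * np.log(pc))
        a_new = float(np.sum(wa) / denom_a) if denom_a > 0 else a
        # cap the Beta shape away from 1: Beta(1, 1) is the uniform null, so
        # an unconstrained shape makes the mixture unidentifiable and eats
        # null mass under pure-null inputs
        a_new = min(max(a_new, 1e-3), 0.5)
        if abs(pi0_new - pi0) < 1e-8 and abs(a_new - a) < 1e-8:
            pi0, a = pi0_new, a_new
            break
        pi0, a = pi0_new, a_new
    cdf = pi0 * pc + (1.0 - pi0) * pc ** a
    q = pi0 * pc / np.maximum(cdf, eps)
    # enforce monotonicity in p (step-up style)
    order = np.argsort(pc)
    q_sorted = np.minimum.accumulate(np.minimum(q[order], 1.0)[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = q_sorted
    return out


def select_candidates(
    bait: str,
    control: str,
    contrast_table: pd.DataFrame,
    fdr_threshold: float = 0.01,
    fdr_method: str = "bh",
    bait_protein: str | None = None,
) -> pd.DataFrame:
    """Candidate interactors of a bait from its contrast against the control.

    Proteins significant at the FDR threshold AND enriched on the bait side
    are candidates; the bait's own row is excluded from the candidate list
    but reported (column ``is_bait_row``).
    """
    mask = (contrast_table["group_a"] == bait) & (contrast_table["group_b"] == control)
    sub = contrast_table.loc[mask].copy()
    if sub.empty:
        raise ValueError(f"no contrast {bait!r} vs {control!r} in results")
    sub["fdr"] = estimate_fdr(sub["p_value"].to_numpy(), fdr_method)
    sub["is_bait_row"] = (
        sub["protein"] == bait_protein if bait_protein is not None else False
    )
    sub["candidate"] = (
        (sub["fdr"] <= fdr_threshold) & (sub["estimate"] > 0) & ~sub["is_bait_row"]
    )
    sub["direction"] = np.where(sub["estimate"] > 0, bait, control)
    return sub


def bait_levels(matrix: QuantMatrix, bait_proteins: dict[str, str]) -> dict[str, float]:
    """Mean pre-imputation log2 intensity of each bait's own row in its own
    samples (bait rows are near-complete by design, so pre-imputation means
    are well defined)."""
    levels = {}
    for bait, protein in bait_proteins.items():
        if protein not in matrix.values.index:
            raise ValueError(f"bait row {protein!r} missing from matrix")
        cols = [s for s in matrix.samples if matrix.groups[s] == bait]
        levels[bait] = float(matrix.values.loc[protein, cols].mean())
    return levels


def proteoform_differential(
    fl: str,
    pr: str,
    contrast_table: pd.DataFrame,
    candidates_fl: set[str],
    candidates_pr: set[str],
    known_partners: set[str],
    bait_level_fl: float,
    bait_level_pr: float,
    fdr_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    fdr_method: str = "bh",
    gene_of: dict[str, str] | None = None,
    bait_proteins: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Bait-corrected differential interactors between FL and PR baits.

    A prey is retained iff: FDR <= ``fdr_threshold``; |log2 difference| >
    ``fc_threshold``; when the prey is enriched on the side of the more
    intense bait proteoform, the prey difference must exceed the bait-level
    difference |Delta bait| (preys on the weaker bait's side are exempt);
    and the prey is a candidate interactor of FL or PR or a known partner of
    the gene.  Output has one row per tested prey with the per-filter
    verdicts and the direction (FL-specific / PR-specific).
    """
    gene_of = gene_of or {}
    mask = (contrast_table["group_a"] == fl) & (contrast_table["group_b"] == pr)
    sub = contrast_table.loc[mask].copy()
    if sub.empty:
        raise ValueError(f"no contrast {fl!r} vs {pr!r} in results")
    if bait_proteins is not None:
        sub = sub[~sub["protein"].isin(bait_proteins)]
    sub["fdr"] = estimate_fdr(sub["p_value"].to_numpy(), fdr_method)
    delta_bait = bait_level_fl - bait_level_pr

    est = sub["estimate"].to_numpy()
    pass_fdr = sub["fdr"].to_numpy() <= fdr_threshold
    pass_fc = np.abs(est) > fc_threshold
    on_strong_side = np.sign(est) == np.sign(delta_bait)
    pass_bait = ~on_strong_side | (np.abs(est) > abs(delta_bait))

    genes = np.array([gene_of.get(p, p) for p in sub["protein"]])
    in_candidates = np.array([
        (p in candidates_fl) or (p in candidates_pr) or (g in known_partners)
        for p, g in zip(sub["protein"], genes)
    ])

    sub["pass_fdr"] = pass_fdr
    sub["pass_fold_change"] = pass_fc
    sub["pass_bait_correction"] = pass_bait
    sub["candidate_or_known"] = in_candidates
    sub["retained"] = pass_fdr & pass_fc & pass_bait & in_candidates
    sub["direction"] = np.where(est > 0, "FL-specific", "PR-specific")
    sub["delta_bait"] = delta_bait
    return sub.reset_index(drop=True)


def frequency_table(
    candidate_lists: dict[str, set[str]],
    differential_tables: dict[str, set[str]],
) -> pd.DataFrame:
    """Prey recurrence across baits and proteoform comparisons.

    Per prey: the number of baits listing it as a candidate interactor and
    the number of FL-PR (or PR1-PR2) comparisons in which it is differential;
    sorted descending.  Highly recurrent preys are likely method background
    rather than true interactors.
    """
    counts: dict[str, list[int]] = {}
    for preys in candidate_lists.values():
        for prey in preys:
            counts.setdefault(prey, [0, 0])[0] += 1
    for preys in differential_tables.values():
        for prey in preys:
            counts.setdefault(prey, [0, 0])[1] += 1
    rows = [
        {"prey": prey, "n_baits_candidate": c, "n_comparisons_differential": d}
        for prey, (c, d) in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["prey", "n_baits_candidate",
                                     "n_comparisons_differential"])
    return df.sort_values(
        ["n_baits_candidate", "n_comparisons_differential", "prey"],
        ascending=[False, False, True], kind="stable",
    ).reset_index(drop=True)


@dataclass
class OverlapStats:
    n_a: int
    n_b: int
    n_shared: int
    pct_shared_of_a: float
    unique_a: set[str]
    unique_b: set[str]


def overlap_stats(candidates_a: set[str], candidates_b: set[str]) -> OverlapStats:
    """Set overlap between two candidate lists; percentage relative to the
    first list, rounded to one decimal."""
    a, b = set(candidates_a), set(candidates_b)
    shared = a & b
    pct = round(100.0 * len(shared) / len(a), 1) if a else 0.0
    return OverlapStats(len(a), len(b), len(shared), pct, a - b, b - a)
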