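# Methods

This note documents the models, rules and numerical choices behind `pfp`,
what the synthetic-data generators emulate, and what passing tests do and do
not establish about real data.

## Catalogue construction

An identified N-terminal peptide is classified by its start position on the
matched protein: positions 1 and 2 are database-annotated translation starts
(position 1 with the initiator methionine retained, position 2 after its
removal), anything beyond position 2 points to an alternative translation
initiation site. Starts at position 2 are checked against methionine
aminopeptidase specificity — iMet removal is expected only when the second
residue is small — with the small-residue set fixed to {A, C, G, P, S, T, V}.
The same logic applies to an alternative start relative to its own
initiator: a start at an internal Met is compliant, a start one residue
after an internal Met is compliant iff the started residue is small.
Non-compliance does not change the classification, only the iMet status
that feeds confidence.

Confidence of an alternative start is `high` iff the N-terminus is mostly
in-vivo Nt-acetylated (PSM fraction strictly above 0.5) or has Ribo-seq
support at an iMet-compliant start; free (chemically acetylated) N-termini
without orthogonal evidence stay `low`. The 0.5 threshold is the same one
used as an evidence item in TIS scoring, keeping the two stages consistent.
Pyroglutamate N-termini are retained and classified by position like any
other peptide.

Merging across proteases keeps one row per unique (primary accession,
start). Multi-mapping accession lists are ordered canonical → isoform →
Ribo-seq, then by higher whole-sample peptide count, smaller start position,
and alphabetical accession (the final key makes ties deterministic).
Modification conflicts resolve in favour of in-vivo acetylated peptides;
spectral counts are summed and the per-N-terminus acetylation fraction is
pooled PSM-weighted.

The taxonomy table counts source class × start class × confidence, with a
region split (annotated CDS / 5'UTR / non-translated region) for
Ribo-seq-derived entries. In the bottom summary the database-annotated TIS
row counts canonical database-annotated starts only, while the alternative
TIS row counts canonical alternative starts plus ALL isoform-only and ALL
Ribo-seq-only N-termini — including isoform starts that are
database-annotated on their own isoform sequence, since relative to the
canonical proteome they still represent alternative proteoforms. This is
the only aggregation that makes the summary rows internally consistent with
the detail cells.

## Proteoform placement and feature deltas

A truncated proteoform is an exact suffix of its reference; suffix matching
is checked before generic substring search because it is unambiguous even
in low-complexity sequence. A 5'-extended proteoform contains the reference
as a suffix of itself. Everything else is placed with a BLOSUM62 overlap
alignment, affine gap costs of −9.5 (opening) and −0.5 (per residue), and
free end gaps. Gap-cost bookkeeping: conventions differ on whether the
first gapped residue pays opening + extension or opening alone; here a gap
of length L costs −9.5 − 0.5·L, and the aligner is configured accordingly.
Below an identity of 0.3 over the aligned span the proteoform is reported
as having no reliable reference; the floor is configurable (within-gene
alignments tolerate a laxer floor than cross-database homology searches).

Truncations lose the reference range [1, start−1]. Extensions gain their
prepended prefix, and any feature spanning reference position 1 or 2 is
reported as lost — it is no longer N-terminal once the extension displaces
the native N-terminus. Features overlapping a lost range are reported with
the fraction of the feature covered; any overlap counts, with the fraction
left to the reader, because the threshold at which a partial loss becomes
functionally relevant is a judgement call the pipeline should not make
silently. Lost and gained sequence stretches are scanned against a motif
regex table; a small built-in ELM-style table ships for tests and demos,
and users supply their own exported motif tables for real analyses.

Processing origin: a truncation is flagged as potential signal / transit /
propeptide processing when its start falls within ± 1 residue of the mature
N-terminus (feature end + 1); the one-residue margin absorbs ragged
processing and off-by-one annotation. Dipeptidase trimming is flagged for
an even number of removed residues up to 8 — dipeptidases remove residues
in pairs, and more than four rounds is implausible; this parity rule is an
operationalization (the underlying annotation practice is not documented
anywhere) and is surfaced as a flag, never silently applied. A user-supplied
(accession, start) table marks known protease cleavage sites. Any raised
flag feeds the TIS-score zero trap.

Molecular weights use average residue masses plus one water, reported in
kD; `X` contributes the unweighted mean residue mass, other unknown
residues raise. The test suite cross-checks against an independent mass
library.

## TIS and gene scoring

The TIS score is a transparent additive evidence count: eleven +1 items
(high confidence, >50% acetylation, spectral count > 1, several peptides at
the same start, database/Ribo-seq TIS evidence, multiple proteases, a
non-AUG 5'UTR start, a lost or gained linear motif, presence in an earlier
N-terminomics compendium, an OMIM disease link, no known interactions),
two +3 items (truncation of less than half the protein; a lost annotated
domain), and a zero trap: any suspicion that the N-terminus stems from
proteolytic processing sets the score to 0 regardless of other evidence,
because a processing product is not a translation product no matter how
well supported the peptide is.

Genes are categorised by their observed starts — (1) annotated +
alternative, (2) multiple alternative, (3) multiple annotated, (4) one
TIS — resolving ties in that order. Gene scores sum the alternative
proteoform scores and are retained for categories 1 and 2, or 4 with
orthogonal cytosolic evidence. The retention threshold is a config key
defaulting to score > 0; the source analyses used both > 0 and > 1 in
different places, so the choice is exposed rather than hidden. Ranking of
retained genes is lexicographic over ordered criteria (extra evidence,
domain/motif delta, truncation length > 20 aa — or > 50 aa for proteins
over 700 aa — cytosolic evidence count, non-structural class, disease
association, in-frame), with the gene score and then the symbol as final
tie-breaks. The structural-vs-non-structural call is supplied as an input
column and defaults to non-structural, since it is a manual judgement.

## NSAF tissue expression

PSMs are filtered (decoys, contaminants, q ≤ 0.01), accession lists sorted
by the cataloguing priority, the best PSM per peptide chosen (acetylated
first, then highest score), and peptides grouped by primary accession into
per-sample proteoform tables. For proteoforms whose primary accession is
non-canonical, peptides occurring as substrings of any canonical protein
are excluded before quantification — shared peptides cannot distinguish the
proteoform from the canonical pool.

NSAF divides each protein's spectral count by its length (longer proteins
yield more peptides) and renormalizes per sample; each sample is a simplex
and log2 NSAF is the modelling scale, with zero-count proteoforms missing
rather than −∞. Differential expression across tissues keeps proteoforms
observed in all replicates of at least one tissue (the filter runs before
model fitting), fits a per-proteoform one-way tissue model on the observed
values, and moderates the per-proteoform variances by shrinking toward a
pooled prior: the prior degrees of freedom and scale are moment-matched on
log s² (inverting the trigamma function by Newton iteration, with the
degenerate no-spread case mapped to infinite prior df), the posterior
variance is the df-weighted mix, and the tissue F test uses the posterior
variance with inflated denominator df. As the prior df goes to 0 the test
reduces exactly to per-proteoform OLS (verified against statsmodels);
infinite prior df pools completely. Pairwise tissue contrasts use the same
posterior variance; both families are Benjamini–Hochberg adjusted with
significance at adjusted p ≤ 0.05.

## Interactome statistics

Preprocessing removes reverse / contaminant / identified-by-site rows,
log2-transforms, and keeps proteins with at least 3 quantified values in at
least one bait group; every stage logs in/out counts so filter survivorship
is auditable.

Missing label-free intensities are treated as left-censored. QRILC-like
imputation regresses, per sample, the observed order statistics on their
censoring-aware standard-normal quantiles (ranks offset by the missing
count), using the upper 75% of observed points where censoring distorts
least, and draws imputations from the truncated lower tail below the
censoring quantile. The alternative is a down-shifted normal per sample,
N(mean − 1.8·sd, (0.3·sd)²). Columns with fewer than 5 observed values
fall back to the shifted normal with a warning. Both are seeded; complete
matrices pass through unchanged.

Each protein is fit with a one-way fixed-effects model over bait labels
(`response = μ + bait + error`); the bait effect is tested by the overall
F test and requested pairwise comparisons by t tests with the pooled
residual variance. A positive estimate means enrichment in the first-named
group; this convention is recorded in every output. Experimental sets
combine one control bait with up to three FL/PR pairs, so the pooled
residual has enough degrees of freedom (14 with seven baits in triplicate)
for stringent FDR thresholds to be attainable.

FDR control defaults to Benjamini–Hochberg. The two-component mixture
alternative fits π₀·Uniform + (1−π₀)·Beta(a, 1) by EM and reports
q(p) = π₀·p / F̂(p), forced monotone in p. The Beta shape is capped at 0.5:
Beta(1, 1) is the uniform null itself, so an unconstrained shape makes the
mixture unidentifiable and absorbs null mass under pure-null inputs; with
the cap, pure-null p-values recover π₀ ≈ 1 and the mixture agrees with
Benjamini–Hochberg. The Gamma-density variant of the mixture is not
implemented — its parameterization is not recoverable and the downstream
logic consumes only the 0.01/0.05 thresholds.

Candidates are preys at FDR ≤ 0.01 enriched on the bait side of the
bait-vs-control contrast, with the bait's own row excluded but reported.
The FL-vs-PR differential filter retains a prey iff FDR ≤ 0.05, |log2
difference| > 1, the prey is a candidate of FL or PR or a known partner of
the gene, and — when the prey is enriched on the side of the more intense
bait proteoform — the prey difference exceeds the bait-level difference.
Bait levels are pre-imputation means of the bait's own row in its own
samples; bait rows are near-complete by design, and post-imputation means
would leak imputation noise into the correction. This double filter removes
expression-difference artifacts (the bait fusion protein itself, and its
constitutive partners, appear significant when FL and PR are expressed at
different levels but rarely pass the fold-change-plus-bait correction).

Since the estimate is a plain group-mean difference in a fixed-effects
model, applying the fold-change filter to the model estimate and to the raw
mean difference is the same thing; no distinction arises.

Frequency tables count, per prey, the number of baits listing it as a
candidate and the number of proteoform comparisons calling it differential;
preys recurring across many unrelated baits are background of the method
rather than true interactors.

## Network assembly

One node per bait proteoform (gene + FL/PR tag) and per prey gene; one edge
per (bait, prey, method). Database support is an edge attribute, not an
edge source — published network edge counts that mix experimental and
database edges are not reproducible without the database exports, so
experimental edges and database-support counts are reported separately.
Self-edges (a prey equal to its bait's gene) are flagged and retained.
Sharing classes (FL-only / PR-only / shared) derive from prey membership
across the FL and PR candidate lists.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the structure the analysis assumes: genes with one
canonical protein, internal-start truncations (start uniform over
[5, 0.9·L]) and 5'-extensions (5–60 residues, stored as isoform or Ribo-seq
entries); protease-specific N-terminal peptides (trypsin after K/R not
before P, chymotrypsin after F/W/Y/L, GluC after E — canonical residues
only, no missed cleavages, since digestion fidelity is not the target);
in-vivo vs heavy (chemical) acetylation sampled per PSM; internal
contaminant peptides with no translational start; interactome matrices with
background proteins sharing a mean log2 intensity (~N(25, 2²) across
proteins, replicate sd 0.3) across all baits, spiked preys, bait rows
present only in their own samples at level 30 plus a configurable offset,
and left-censoring P(missing | x) = logistic(2·(limit − x)) with the limit
at the 5th percentile of generated intensities; and tissue spectral counts
Poisson with rate ∝ multiplier × length × depth so the NSAF length
correction is testable. One pseudo-random substream per operation is
derived from the master seed by a named label, so adding an operation never
perturbs another's draws, and fixed seeds give bit-identical outputs.

Not emulated: spectrum-level noise, retention time, search-engine score
distributions and FDR search, peptide-level interference, correlated
background structure between baits, and compositional effects beyond NSAF
normalization. Passing tests therefore demonstrate that the statistical
machinery is correct under its stated model — error rates controlled,
estimators unbiased, rules applied exactly — not that the model captures
every pathology of real LC-MS/MS data.

## Problem sizes and defaults

Simulation-based checks use 400 background proteins, 7 baits × 3
replicates, +3 log2 spike effects and 20 seeds for recovery; 100-protein
× 20-seed (≥ 2,000 null proteins) batches for false-positive rates; and
300-proteoform tissue matrices for NSAF properties. These sizes give
binomial standard errors small enough for the 3-SD acceptance bands while
keeping the full suite in seconds. All thresholds (valid-value minimum,
candidate FDR 0.01, differential FDR 0.05, fold-change 1.0, imputation
shift 1.8 / spread 0.3, identity floor 0.3, processing margin ±1,
gene-score threshold > 0) are config keys with the stated defaults.

## Known limitations

- The dipeptidase parity rule and the high/low-confidence operationalization
  are stated interpretations of under-documented practice, exposed as flags
  and config rather than buried.
- The mixture FDR is a uniform–Beta EM fit with a capped shape; it is a
  pragmatic monotone q-value, not a maximum-likelihood density estimate.
- The moderated tissue test assumes independent proteoforms; NSAF
  normalization induces weak negative dependence across proteoforms within
  a sample, which Benjamini–Hochberg tolerates but does not model.
- `restrict_noncanonical` rescales spectral counts proportionally when a
  proteoform loses part of its peptides; per-peptide PSM counts would be
  more precise where the PSM table is still available.
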