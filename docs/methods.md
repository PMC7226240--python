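# Methods

This note documents the models, statistical procedures, and design
choices behind the `cementome` package, and what its synthetic-data
experiments do and do not demonstrate about real data.

## Study design being modeled

The pipeline analyzes label-free (SWATH) protein quantitation of two
tick tissues — salivary glands (the *sialome*) and the cement cone (the
*cementome*) — across three adult female feeding stages: T1 (14–17 days
post-infestation, just after molting), T2 (18–20 dpi, secondary cement
production) and T3 (21–25 dpi, just before detachment).  Three sample
types are quantified: salivary-gland lysate ("native" extraction) and
cement extracted with SDS and with urea.  With 3 stages × 2 biological ×
3 technical replicates per sample type, the full design is 54 LC–MS
runs.  Abundances are Total Area Sums (TAS): per-protein summed
extracted-ion chromatogram peak areas.

## Normalization

Global normalization rescales every run (column) so its summed TAS
equals the grand mean of the raw run totals.  Any common target constant
would preserve within-run proportions; the grand mean is chosen so
normalized values stay on the raw scale.  The operation is idempotent
and rejects all-zero runs.

Total-sum normalization carries a compositional caveat: it only reflects
instrument loading when the *biological* total is stage-stable.  If
up-regulated mass does not cancel down-regulated mass, closure pushes an
artifactual opposite trend into every protein's normalized profile.
This is inherent to the method (and to the real analysis it reproduces);
see the generator section for how the simulation handles it.

## Differential representation

Per protein and per pairwise stage comparison (T1vT2, T2vT3, T1vT3) a
two-sided pooled-variance Student's t-test is applied at α = 0.05, with
no multiple-testing correction (an optional Benjamini–Hochberg flag
exists but is off by default, matching the raw p < 0.05 convention).
The replicate unit defaults to `run`: all biological × technical runs
enter as observations (n = 6 per stage).  **Caveat:** technical
replicates of one biological replicate share the biological draw, so
with appreciable biological variance the run-level test is
pseudo-replicated and its type-I rate exceeds the nominal α.  The
`bio_rep_mean` option averages technical replicates first (n = 2 per
stage) and is calibrated, at the cost of power.  Both units are exposed
because the underlying design is ambiguous about pooling.

Identical constant groups report t = 0, p = 1 ("no evidence of
change"); groups with fewer than two observations are flagged
untestable, never silently dropped.  One-way ANOVA follows the classical
sums-of-squares decomposition; all-constant equal-mean input is reported
as F = 0, p = 1 by convention.

## Profile classification

A protein significant in at least one comparison is *differentially
represented* and is assigned to a developmental-process category by its
significance/direction triple over (T1vT2, T2vT3, T1vT3); a protein with
no significant comparison is assigned to housekeeping.  The category
profile shapes are described in the literature only graphically, so the
shipped template table is an explicit in-package reconstruction
(`data/profile_templates.json`, user-editable):

| category | signature | trajectory (log-effect units at T1,T2,T3) |
|---|---|---|
| housekeeping | (ns, ns, ns) | 0, 0, 0 |
| molting | (down, ns, down) (+ all-down) | 1, 0, 0 |
| secondary cement production I | (up, down, \*) | 0, 1, 0 |
| secondary cement production II | (up, ns, up) | 0, 1, 1 |
| cement maintenance | (ns, down, down) | 1, 1, 0 |
| feeding | (up, up, up) | 0, ½, 1 |
| feeding and oogenesis | (ns, up, up) / (ns, ns, up) | 0, 0, 1 |
| detachment | (down, up, ns) | 1, 0, 1 |

Detachment is given the distinct T2-dip triple so that the table is
total and unambiguous — a "T3 spike" reading would collide with feeding
and oogenesis.  Triples not listed resolve to the nearest signature
under a flip-type-aware edit cost: reading a template "ns" as
significant costs 1 (a type-I event, probability ≈ α), a missed
detection costs 4, a sign inversion 16.  At the design's power a single
α-level flip is overwhelmingly the most likely explanation of an
off-template triple, which plain Hamming distance ignores (it would
send (down, up, up) to feeding — the least likely origin).  Remaining
ties break by a fixed priority order (molting first, detachment last).

Every trajectory spans exactly one `effect_size` unit between its
extreme stages, so "effect size 4" means a 4-fold change between the
lowest and highest stage of every non-housekeeping category (feeding
rises √4-fold per step).

## Synthetic-data generator

Abundances are log-normal around category trajectories:
`x = exp(base + traj·ln(effect_size) + ε_bio + ε_tech)` with
`σ = sqrt(ln(1+cv²))` per noise layer, `base ~ N(mean_log_abundance,
log_abundance_sd²)`.  Proteins carry an origin (tick/host), a tissue
membership (sialome-only / cementome-only / shared), cement extraction
membership (SDS, urea or both), a sequence class (uniform background or
Gly-rich with 30–45 mole-% Gly, emulating the glycine-rich cement
protein superfamily), and 1–3 GO biological-process terms from a
Zipf-weighted vocabulary.  Host proteins concentrate 86% of their mass
in feeding-and-oogenesis and the two secondary-cement templates, and
concentrate in the cementome.  Absences are true zeros.

**Compositional balance.**  Because total-sum normalization assumes a
stage-stable total (above), the generator controls the *realized* —
not just expected — total abundance of every run type:

1. per dataset, a penalized quadratic program finds category mass-share
   targets for each tick origin × membership × extraction cell, closest
   to uniform, such that each run type's mixture (including the fixed,
   deliberately unbalanced host tilt) has a stage-stable expected total;
2. categories are assigned by randomized mass-quota within each cell —
   walking proteins in descending abundance, each is drawn with
   probability proportional to the category's remaining mass deficit;
3. minimum-norm per-protein log-abundance adjustments (a few Newton
   steps) zero the residual stage drift of every run type exactly
   (discrete assignment cannot split a dominant protein's mass).

Without this control, realized stage drifts of 0.1–0.4 log units leak
through normalization into every profile and classification collapses;
with it, drift is ≈ 0.02 log units, well under the t-test's detection
scale.  Passing explicit `category_weights` disables the balance solve
(useful for deliberately unbalanced experiments).

What the generator does **not** emulate: peptide-level roll-up and the
3-peptide quantitation filter, missing-not-at-random dropout,
correlated protein families, run-order drift, real GO annotation
structure, or a proteome whose regulation is *not* mass-balanced.
Recovery results therefore show the pipeline is correct under its own
normalization assumption, not that the assumption holds for any real
dataset.

**Parameter-recovery experiment.**  At the reference conditions
(n = 200 proteins, effect size 4, run-level cv 0.1, no biological
layer), classification recovers a mean 96.3% of true categories over 30
seeds (min 93%).  The residual errors are α-level flips forced by the
differential-representation gate (a housekeeping protein with one false
positive must be assigned somewhere) and symmetric single-flip
ambiguities (e.g. maintenance vs secondary-I).  The acceptance check
reports the mean over five independent datasets.  With effect size → 1
the non-housekeeping fraction approaches the joint type-I rate of the
three correlated t-tests (~0.12–0.14, estimated by direct Monte Carlo).

## Partition arithmetic and key-protein selection

The cementome is the unique-accession union of the SDS and urea
extraction sets; accessions are opaque strings and merging is exact
string equality.  The worked example
(`partition.example_identification_sets`) reproduces the published
identification arithmetic: 62 shared proteins (13 tick + 49 host), 81
tick cementome proteins (13 + 68), and a 654-protein cementome from
disjoint 388 + 266 extraction sets.  That the two extraction sets are
exactly disjoint is a counting convention of the original identification lists, noted
here and encoded in the fixture.

Key proteins are scored 0–4 on: shared sialome/cementome membership;
top-2 mean normalized TAS within a non-housekeeping category (ties at
the boundary keep all tied proteins); any annotated GO process holding
> 4% of the (protein, process) annotations in the analyzed set (an
alternative per-protein denominator is a flag); and betweenness
centrality above a configurable quantile (default top 10% — no published
cutoff exists).  A missing centrality table skips that criterion
with a flag rather than scoring false.

## Co-occurrence network (SparCC + betweenness)

Relative abundances are compositional, so association is inferred with
SparCC: from the variation matrix `t_ij = var(log(x_i/x_j))` the basis
variances solve the linear row-sum system `M ω² = t·1` (equivalently,
the least-squares fit of `t_ij ≈ ω_i² + ω_j²` under the sparsity
assumption), then `ρ_ij = (ω_i² + ω_j² − t_ij)/(2 ω_i ω_j)`, clipped to
[−1, 1].  The most-correlated pair above the exclusion threshold
(default |ρ| > 0.1) is iteratively removed from the system and the
variances re-solved, until no pair exceeds it (max 10 iterations).
Because the input is continuous intensity rather than counts, SparCC's
Dirichlet resampling is omitted; a pseudocount (default 1 TAS unit)
guards zeros.  Optional permutation bootstrap p-values shuffle each
component's runs independently.  Components solving to non-positive
basis variance are flagged unreliable and masked.

Networks keep edges with |ρ| ≥ 0.6 by default (no published
threshold; a 0.4/0.6/0.8 sensitivity count is emitted).  Betweenness
centrality (BNC) runs on distances `d = 1 − |ρ|` (sign kept as an edge
attribute), unnormalized by default: the score is the number of
unordered node pairs whose shortest paths cross the node, with
fractional credit for ties.  Isolated nodes score 0.

## Physicochemical panel

All calculators are implemented in-package and cross-checked in tests
against an independent reference implementation (Biopython's ProtParam)
to ≤ 1e-3:

- amino-acid mole-%, X excluded from denominators and counted;
- theoretical pI: Henderson–Hasselbalch net charge over termini and
  D, E, C, Y, H, K, R with the Bjellqvist pKa set (including
  residue-specific terminal overrides), root by bisection on [0, 14] to
  1e-4;
- GRAVY: mean Kyte–Doolittle hydropathy (reversal-invariant);
- instability index: (10/L)·Σ DIWV over ordered dipeptides, unstable
  above 40 (not reversal-invariant); the published DIWV table is
  vendored at `data/diwv.json` (Guruprasad, Reddy & Pandit 1990);
- aliphatic index: X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu));
- atomic composition: residue formulas minus (L−1) waters.

The amino-acid ratio screen flags residues whose cement/non-cement
mole-% ratio is ≤ 0.5 or ≥ 1.5, boundaries inclusive; a zero
denominator reports an infinite, flagged ratio.  Group summaries follow
the four comparison groups (host, tick, host cement, tick cement), with
the tick group subsampled to 100 proteins under a fixed seed.

## SEM–EDS and α-Gal ELISA

EDS atomic-% tables are summarized per element × tissue: stage means,
abundance class (high > 10 atomic %, low < 1 atomic %, mid between,
rare = detected in fewer than 2 samples and excluded, as applied to
sporadic Br/Zn), and one-way ANOVA across stages on the area scans.
Protein-group atomic composition is correlated with the T1–T3 mean EDS
composition over the shared elements (C, N, O, S; hydrogen is invisible
to EDS, so protein percentages are renormalized over C/N/O/S) by
Spearman rank correlation with average-rank ties.  The synthetic EDS
generator derives each sample's composition from the abundance-weighted
atomic composition of its member proteins plus Gaussian scan noise,
renormalized to 100%.

ELISA calibration fits OD₄₅₀ = intercept + slope·ng by OLS on
blank-corrected standards over the 0.0–1.0 ng working range.
Quantitation per sample: average the 3 replicate ODs, subtract the mean
blank, invert the line, floor negatives at 0 with an audit flag, and
scale to ng α-Gal per 1 μg coated protein (100 ng per well by default,
×10).  With zero noise this is an exact inverse of the plate generator.
Group comparisons use Welch's t-test (unequal variance,
Welch–Satterthwaite df) pairwise and one-way ANOVA across stages.

## Numerical conventions and degenerate inputs

- Sample variances use ddof = 1 throughout.
- pI bisection tolerance 1e-4; variation matrices are clipped at 0 and
  symmetric by construction; ρ clipped to [−1, 1].
- Equal means with zero variance ⇒ t = 0, p = 1 (and F = 0, p = 1).
- Top-k ranking ties keep all tied proteins; category-summary
  percentages sum to 100 per origin; empty groups yield empty rows,
  never division errors.
- All randomness flows from explicit integer seeds; a fixed seed gives
  byte-identical serialized outputs.

## Problem sizes

Defaults keep the full test suite under a minute and the acceptance
script under ~15 s: 200-protein datasets for recovery (5 replicates),
800 proteins for the null arm, 500–1000 runs for SparCC checks, 100
random graphs (≤ 8 nodes) for the centrality oracle, 1000 proteins for
type-I simulations, and 20 random sequences for the reference
cross-check.  These sizes give Monte-Carlo standard errors well inside
the tolerances asserted.

## Known limitations

- The category template table is a reconstruction; real profile shapes
  may differ, and tissue-specific multi-assignment is out of scope (one
  best category per protein).
- The run-level t-test inherits the pseudoreplication caveat above.
- SparCC here omits Dirichlet resampling and uses a fixed pseudocount;
  very sparse matrices (many zeros) would need the count-based variant.
- GO annotations are consumed, never computed; origin labels are taken
  as given.
- The ELISA model is linear through the working range; saturation and
  hook effects are not modeled.
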