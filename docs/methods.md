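# Methods

## Problem and model

`evmir` analyses miRNA-level read-count matrices from a paired-compartment
design: for each donor, a small-RNA library from the producing cells and one
from their extracellular vesicles (EVs), each under two culture conditions
(normoxia, 21% O2; hypoxia, 5% O2). The scientific question is whether the
differential miRNA cargo of EVs between conditions merely mirrors cellular
expression changes, or reveals selective sorting — favored loading into EVs
or retention in the cells.

All inference starts from integer counts; abundance is counts per million
(CPM), `counts_ij / L_j * 1e6`, with the library size `L_j` defaulting to
the per-sample column sum of the supplied miRNA matrix (an explicit
`library_size` column in the sample sheet overrides it — use this when the
matrix has been filtered after quantification).

## Presence rule

A donor *detects* a miRNA when its raw count reaches `min_count` (default 1
read, the minimum supporting count typical of miRNA quantification); a
(compartment, condition) group *identifies* it when at least `min_donors`
donors detect it (default 2 of 3). For donor numbers other than three the
default generalizes to `ceil(2n/3)`, which reproduces 2-of-3 at n = 3.
Detection uses raw counts, not CPM: the rule guards against single-donor
artifacts, and a read-count floor is the natural scale for that. Two
samples of one donor in the same group are rejected rather than merged —
donor-level detection would be ill-defined.

## Differential enrichment

A miRNA is differentially enriched (DE) between two groups on one of two
bases:

- **qualitative** — identified in exactly one group (exclusivity); such
  miRNAs never receive p-values, their evidence is the presence rule;
- **quantitative** — identified in both groups ("tested") with
  |log2FC| > 1 and FDR ≤ 10%.

The quantitative engine is a fixed-dispersion negative-binomial
likelihood-ratio test, chosen for being specifiable in closed mathematical
terms and checkable against a brute-force likelihood maximizer (which the
test suite does): counts_ij ~ NB(mean = L_j · μ_g, variance =
mean + φ·mean²) with one rate per group under the alternative and a shared
rate under the null; the LR statistic is referred to χ²(1). At φ = 0 the
model reduces to Poisson and the rate MLE is the pooled-count over
pooled-library ratio; for φ > 0 the rate is fitted by 1-D Brent
maximization in log μ.

Fold change is computed on the CPM scale with a pseudocount,
`log2((μ_b·1e6 + c)/(μ_a·1e6 + c))`, c = 0.5 CPM by default, so a tested
miRNA with a zero group mean (possible when detection is sub-threshold)
still has a finite log2FC.

**Dispersion** is a method-of-moments estimate: counts are scaled to the
mean library size, residuals taken about each group's mean, and
`φ_i = max(floor, (s²_i − m̄_i)/m̄_i²)` with floor 1e-6. The default mode
shrinks each φ_i halfway toward the across-feature median (`common` mode
uses the median alone); the midpoint is a deliberately simple compromise
between per-feature noise at n = 3 and a single shared value. Groups with
a single replicate require a caller-supplied fixed φ.

**Multiplicity**: Benjamini–Hochberg, applied per contrast across exactly
the tested set of that contrast. The FDR gate is *inclusive* (q ≤ 0.10) by
default while the fold-change gate is strict (|log2FC| > 1); the inclusive
comparator admits a boundary call at exactly 10% FDR, which is how such
borderline calls are conventionally reported in this setting. Both are
configurable (`fdr_inclusive`, `lfc_threshold`, `fdr_threshold`).

## Compartment calls and dynamics classification

Per condition, from the EV-vs-cell contrast (oriented cells → EVs): a miRNA
is **enriched in EVs** when exclusive to EVs or tested with log2FC > 1 and
the FDR gate passed, **retained in the cells** when exclusive to cells or
log2FC < −1, **neutral** otherwise, **absent** when identified in neither
compartment.

Every miRNA DE in the EV contrast (H-EVs vs N-EVs) is then classified. For
a miRNA up in H-EVs (mirror everything for down):

1. **concurred** — also DE in the cell contrast, same direction: the EV
   change reflects the cellular change;
2. **favored loading** — not concurred, and enriched in EVs in hypoxia.
   This deliberately covers opposite-direction cell calls (a miRNA down in
   H-cells yet enriched in H-EVs is the strongest loading evidence), not
   just "no cell change";
3. **retention** — not 1–2, and retained in the cells in *normoxia*:
   retention in the opposite condition depresses the miRNA's EV level
   there, producing the relative excess;
4. **unexplained** otherwise.

"No change in the cells" means no DE call of either basis, including
miRNAs absent from the cells entirely. The priority order (concurred
first) resolves miRNAs matching several mechanisms into a single class
while `flags` retains every matching mechanism, so no information is lost.
Requiring EV-enrichment evidence for favored loading (rather than
inferring it from the cell no-change alone) is the stricter of the two
defensible readings; it trades a little sensitivity for specificity.

The Venn sets (enriched/retained × both/normoxia-only/hypoxia-only) are
disjoint by construction. The summary reports the selective fraction
(favored loading + retention) / (EV-DE miRNAs); it is null (not 0) when no
miRNA is EV-DE.

## Synthetic data generator

The generator emulates the emitting design — 3 donors × 2 compartments ×
2 conditions, ~100–150 identified miRNAs per group, library sizes around
2×10⁶ (lognormal, CV 0.2), NB dispersion φ = 0.1, donor random effect 0.25
log2 units, baseline abundance log2 CPM ~ Normal(5, 2) — with planted
per-miRNA classes at effect 2.5 log2 units. Effects are injected on log2
relative abundance and the abundance vector renormalized per sample
(compositional closure, Σ_i a_ij = 1), which reproduces the compositional
nature of CPM: a large planted effect slightly perturbs all other features.
Tests that check planted magnitudes therefore difference planted against
null features, which cancels the per-sample renormalization exactly.

With probability `exclusive_fraction` (default 0.3) a planted effect is
realized qualitatively as structural zeros instead of a fold change,
modeling the many exclusivity-based calls such designs produce: concurred
classes zero both compartments of the down-regulated condition; retention
zeroes the depleted EV group; favored loading makes the feature present
*only* in the loaded EV group. The favored-loading realization is the one
choice that keeps the planted mechanism identifiable from the data — an
EV-only exclusive species is loading evidence, whereas zeroing only the
opposite EV group would leave no EV-vs-cell signal in either condition.

What the generator does **not** emulate: isomiR structure, sequence-level
effects, donor-by-condition interactions, correlated miRNA families, and
compositional competition stronger than the planted effects themselves.
Passing recovery tests therefore show that the inference chain is correct
under its own model assumptions, not that those assumptions hold for any
real dataset.

## Target layer

Top-k selection ranks the EV-enriched miRNAs of one condition by mean CPM
over that condition's EV samples (ties broken lexicographically). Target
multiplicity is an exact tally over a GMT-encoded miRNA→target map.
Over-representation is the hypergeometric upper tail P(X ≥ k) per pathway
with BH adjustment across tested pathways — a deliberately transparent
standard ORA; the gene universe defaults to the union of pathway genes and
can be given explicitly, and pathway families can be excluded by name
prefix via configuration (nothing is hard-coded).

## Numerical choices

- Rate MLE: Brent in log μ (xtol 1e-12) bracketed around the pooled ratio;
  all-zero groups short-circuit to μ̂ = 0 with log-likelihood 0.
- LR statistics are clipped at 0 before the χ² tail.
- p = 1 and log2FC = 0 for features all-zero in both groups (these are
  normally `absent` upstream and never reach the test).
- Orientation antisymmetry (swapping the contrast groups negates log2FC
  and preserves p) holds to optimizer tolerance (~1e-6), not machine
  epsilon: the dispersion moments concatenate the groups in order.
- Determinism: all randomness flows through one `numpy` Generator seeded
  from the config; identical seed and config give byte-identical counts,
  truth and report payloads.

## Problem sizes

The bundled analysis and the acceptance script use 150 miRNAs × 12 samples
with 10 planted miRNAs per class, and 2,000 features for the null
calibration — sizes at which every stage's behavior (presence, both DE
bases, all four dynamics classes, calibration) is exercised with stable
statistics while the full chain runs in seconds.

## Known limitations

- The NB-LRT with χ²(1) calibration is asymptotic; at 3 replicates the
  null p-value distribution deviates slightly from uniform (KS distance
  ~0.02–0.04 at the default settings), conservative enough that the null
  false-call rate stays well under control.
- No TMM/upper-quartile normalization and no donor-paired or covariate
  models: library-size scaling only, matching the design this package
  targets.
- Exclusivity is not gated on abundance (no CPM floor); a miRNA scraping
  the presence rule in one group can be called qualitatively DE.
- The dynamics classes are rule-based, not model-based: no posterior
  probability accompanies a class label. `flags` is the honest record of
  ambiguity.
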