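# Methods

## Data model

A dual-ortholog library pairs every *S. pyogenes* Cas9 guide with every
*S. aureus* Cas9 guide (`n_sp × n_sa` constructs). Guides carry a category —
`targeting`, `non_targeting`, `essential_control`, `safe_harbor` — and
constructs are classified from their two guides' categories alone:
`gene_gene`, `same_gene`, `gene_control`, `control_control`. Only
non-targeting guides act as negative controls by default; safe-harbor guides
cut the genome and are excluded from the control set (configurable), and
essential controls are used for QC, not for scoring.

## Normalisation

Counts are scaled to reads per million within each sample and log2-
transformed with a pseudocount of 1 added to the RPM (the prevailing
pooled-screen convention; keeps zero counts finite and makes LFC exactly
invariant to per-sample sequencing depth). The reference is the plasmid pool
(pDNA); when several pDNA samples exist their log2-RPM values are averaged
(equal weight regardless of depth, rather than summing counts). Replicates
are averaged at the LFC level before interaction scoring; per-replicate LFCs
are retained for QC. The reference sample set is a configuration field, so an
early cell timepoint can be designated instead of pDNA.

## Interaction scoring

Each guide's **base LFC** is its mean LFC over pairings with opposite-
ortholog negative controls; guides with no scored control pairing are
omitted (their combinations then lack a regressor and are excluded from the
affected fits and from construct counts). For each anchor guide the LFCs of
its combinations with **all targeting partners** (including same-gene
partners) are regressed on the partners' base LFCs by ordinary least
squares. Anchors with fewer than `min_anchor_partners` (default 10) usable
points, or a zero-variance regressor, are dropped and logged — a two-point
line is uninformative. Residuals are z-scored within each anchor using the
sample standard deviation (ddof = 1); when the residual sd falls below 1e-8
the anchor's z's are set to 0 and flagged degenerate.

Gene-pair aggregation: with `n` the number of constructs targeting the pair
(I, J) across both Cas9 arrangements,

    S_I = Σ z (anchored at I's guides) / √n,  S_J likewise,
    z_gene = (S_I + S_J) / √2.

`z_gene` is symmetric in the gene labels by construction. Pairs whose z rows
survive in only one orientation keep that orientation's `S` as `z_gene` and
are flagged `asymmetric` (no √2 combination of a single orientation).
Same-gene "pairs" have a single anchor gene; they receive
`Σ z / √(2n)` for QC visibility, are flagged `same_gene`, and are excluded
from hit calling, screen averages and FDR by default.

## Null distribution of z_gene — a known overdispersion

The two orientations score the *same* constructs: the residual of construct
(i, j) from anchor i's fit and from anchor j's fit both contain that
construct's measurement noise. With base LFCs averaged over `k` control
pairings (k = 14 at the default design), the orientation correlation under a
no-interaction null is approximately

    rho ≈ 1 / (1 + 1/k) ≈ 0.93,

so Var(z_gene) = (1 + rho) ≈ 1.9 rather than 1 — dividing the orientation sum
by √2 assumes independent orientations. A 200-gene null simulation at default
settings measures sd(z_gene) ≈ 1.41, Kolmogorov–Smirnov statistic ≈ 0.08
against N(0, 1), and ≈ 0.3% of null pairs below z = −4 (vs 0.003% for a
calibrated normal). This is a structural property of the statistic, not of
the noise level (the ratio is scale-free). Consequences: the z = −4 cut is
more permissive than its nominal normal tail suggests, and the normal-based
p/q values are anti-conservative near the tail; they are labelled
method-dependent in outputs. We deliberately do not rescale the score — the
published form is the interface — but `analysis/03_null_calibration.py`
quantifies the overdispersion for any configuration.

## Hit calling

* **synergistic**: `z_gene < z_cut` (default −4).
* **synergistic lethal**: additionally mean pair LFC < `lethality_cut`
  (default: the mean over gene-pair mean LFCs of the same condition — the
  "average LFC" dotted line of a screen's LFC/z scatter; a fixed value or a
  construct-level mean are configurable).
* **compensatory non-lethal**: synergistic, mean pair LFC ≥ `lethality_cut`,
  and both single-knockout LFCs > `positivity_cut` (default +0.5). This
  operationalises the narrative pattern of paralog pairs whose single losses
  improve fitness (single-KO LFCs ~ +0.9 to +1.8) while the double knockout
  returns to ~0 without dropping out.
* **buffering**: `z_gene > |z_cut|`; **neutral** otherwise.

Single-knockout LFC per gene = mean LFC over all of its gene-control
constructs (both orientations). Pair-level FDR: one-sided (depletion) normal
p from `z_gene`, Benjamini–Hochberg within condition over distinct-gene
pairs; the procedure tag is recorded in run metadata because any conclusion
at a fixed FDR threshold depends on this (minimal, standard) choice. The
per-pair Mann–Whitney test is exact (full enumeration distribution) when
both groups have ≤ 8 observations and no ties, otherwise a tie-corrected
normal approximation without continuity correction (identical groups give
p = 1). Top-hit ranking: synergistic-lethal pairs by ascending z, ties by
ascending mean LFC, then lexicographic pair name.

## QC

Replicate concordance: Pearson r between per-replicate LFC vectors within a
condition (≥3 shared constructs). Ortholog concordance is computed at the
gene level — per-gene mean base LFC of SpCas9 guides against SaCas9 guides —
because base LFCs are the cleanest per-ortholog single-knockout estimates;
Spearman is available behind a flag. Control separation reports per-category
medians and (median_NT − median_essential) / pooled MAD.

## The simulator

`simulate_screen` draws plasmid representation (lognormal, sigma 0.5),
per-guide cutting efficiency (Beta, mean 0.8, concentration 10), additive
per-gene fitness per doubling (a configurable fraction of essential-like
genes at −0.30..−0.05, beneficial genes at +0.02..+0.09, controls at 0,
essential controls at −0.30) and pairwise epistasis eps (per doubling,
distinct targeting genes only). Construct growth is

    g_c = e_sp f_sp + e_sa f_sa + e_sp e_sa eps,

the efficiency product expressing that a non-cutting guide cannot produce
epistasis. After T doublings (default 21: 21 days at a 24 h doubling time;
~16.8 emulates a 30 h line) relative abundance is renormalised — a screen
measures composition, not absolute growth — and counts are drawn negative-
binomially (Var = μ + 0.09 μ²) at 1000 reads per construct per sample, with
multinomial (exact-depth) and Poisson modes for tests. All randomness flows
from one seed through named substreams, so identical configurations give
byte-identical counts. `expected_lfc_oracle` returns the closed-form
infinite-depth LFCs and is the independent oracle for pipeline tests.

The NB dispersion (0.09) and pDNA sigma were **calibrated, not measured**:
chosen once so that a default duplicate screen reproduces replicate Pearson
correlations of ~0.93–0.95, the range typical of well-executed screens of
this design. What the simulator does not model: PCR jackpotting, cassette
recombination/guide swapping, multiple infection, batch effects, or
position/chromatin effects on cutting — so passing tests demonstrate
correctness of the scoring machinery under the stated generative model, not
robustness to those artefacts in real data.

## Problem sizes and numerical choices

Tests and the acceptance script use a 200-gene (173,056-construct) screen
for null calibration, the 39-gene / 8,836-construct validation-library
geometry for power runs (25 seeds), and the full 552 × 552 catalog
(304,704 constructs) for combinatorics — sizes chosen so the whole suite
runs in well under a minute per stage on one CPU. Floating-point outputs are
written at 6 significant digits; full precision is kept in memory.
Determinism: identical inputs and configuration give bit-identical tables;
hit ranking uses a stable sort with explicit tie-breaks.

## Known limitations

* The null overdispersion above: z_gene is not N(0, 1) under the null, so
  nominal tail probabilities at the z = −4 cut are optimistic by roughly an
  order of magnitude.
* Base LFCs estimated from 14 control pairings carry ~1/√14 of a construct's
  noise into every fit involving that guide.
* The compensation label depends on `positivity_cut` and on the
  screen-average lethality line; both are configuration, not biology.
* Normal-tail FDR q-values inherit the overdispersion; treat absolute FDR
  thresholds as method-dependent.
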