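# Methods

`hqsar` implements a small-panel QSAR workflow of the kind used to relate
molecular-descriptor profiles of BCRP (ABCG2) substrates to a cellular
response — here, the uptake rate of Mitoxantrone in HEK cells expressing one
of the residue-482 polymorphs (482R wild type, 482G, 482T), normalised as
percent of the Mitoxantrone-alone control. The package does not compute
descriptor values from structures; it starts from a user-supplied (or
synthetic) compounds × descriptors table in which every descriptor carries
one of six class labels: constitutional, topological, geometrical,
electrostatic, thermodynamic, quantum-chemical.

## Model

For a chosen descriptor subset S of size k the model is ordinary least
squares with an intercept,

    y_i = b0 + sum_{j in S} b_j x_ij + e_i ,

reported with the statistics a descriptor-model listing prints: per term the
coefficient X, its standard error DX = sqrt(s² [(XᵀX)⁻¹]_jj) and t = |X|/DX
(signs live in X; t is reported as a magnitude), and per model N, R² =
1 − RSS/TSS, s² = RSS/(N − k − 1), the overall F = (R²/k)/((1 − R²)/(N − k − 1)),
and the leave-one-out Q² = 1 − PRESS/TSS. PRESS uses the hat-matrix identity
e_loo,i = e_i/(1 − h_ii); if any leverage exceeds 1 − 1e-8 the implementation
falls back to N explicit refits. Fits go through a QR decomposition of the
design; the explicit normal-equations solution exists in the test suite only,
as an independent oracle.

Degenerate conventions, chosen to keep subset searches NaN-free: a constant
response gives R² = Q² = 0 and zero coefficients (with a warning); a
numerically perfect fit (RSS ≤ 1e-24 · TSS) is clamped to RSS = 0, making
s² = 0, every t = +inf and F = +inf.

## Descriptor preselection

Computed on training compounds only — test compounds never influence any
selection statistic:

1. **Completeness** — drop any descriptor with a missing training value.
2. **Variance** — drop descriptors whose training range is ≤ `invariant_tol`
   (default 1e-12).
3. **Near-duplicate collapse** — connect every descriptor pair with training
   |Pearson r| > `r_dup` (default 0.99), and within each connected component
   keep only the member with the largest |correlation with y| (ties go to the
   earlier column). The stated motivation for excluding very high
   intercorrelations is that they produce over-optimistic regressions.

The companion threshold of 0.8 is interpreted as a *co-occurrence* cap: two
descriptors with training |r| > `r_pair` (default 0.8) may survive
preselection but never appear together inside one model. An alternative
reading — a minimum single-descriptor response correlation of 0.8 — was
rejected because at N = 18 it would eliminate essentially every descriptor.
Both thresholds are configurable.

## Subset search

A staged beam search over the preselected descriptors:

* size 1: fit every descriptor, rank by R², keep the top `beam_width`
  (default 50; a width ≥ C(d, k) makes the search exhaustive, which the test
  suite verifies against full enumeration on 12 × 8 instances);
* size k: extend each kept subset by every compatible descriptor (the
  co-occurrence cap), refit, discard candidates whose weakest descriptor t
  falls below the two-sided critical value at α = 0.05 with N − k − 1 df
  (`t_min="auto"`; a fixed number, including 0, replaces the gate), rank the
  survivors by R² and keep the top `beam_width`;
* stop at `max_size` — by default floor(N/3), mirroring the rule of thumb
  that a final model should carry fewer descriptors than a third of the
  molecules (N = 18 gives 6);
* a backward-refinement sweep then proposes every single-term deletion from
  each per-size winner as a candidate one size down (same t gate), repeating
  top-down until stable. Forward growth alone can carry the best subset only
  inside a superset; deletion recovers it. With an exhaustive beam the sweep
  is a no-op, since nothing can beat a per-size exhaustive optimum.

Within a stage, ranking by R² is equivalent to ranking by F (F is monotone
in R² at fixed k and N). Candidate screening runs on a precomputed Gram
matrix for speed; every model that leaves the search is refit by QR.

### Final-model choice

R² can only grow with size, so "highest R²" (or "highest F") across ladder
sizes would routinely absorb one spuriously significant extra descriptor:
the best size-(k+1) candidate is a maximum over ~d extensions, making its
weakest t an extreme order statistic rather than an ordinary t — at d ≈ 38
candidates and α = 0.05 at least one spurious extension survives the stage
gate in most data sets. The choice rule therefore demands selection-level
significance: a ladder size is *eligible* only if

* Q² ≥ `q2_min` (default 0.5, the usual leave-one-out acceptability bar),
  and
* every descriptor term's t exceeds the two-sided critical value at
  `alpha_enter` (default 0.05) Bonferroni-corrected over
  (candidate descriptors × growth steps).

Among eligible sizes the model with the highest overall F is chosen (ties
break to the smaller size), consistent with ranking final models by F and t.
If nothing is eligible the most stable model (highest Q²) is returned with
`gates_met: false` in the audit, rather than raising — a pipeline should see
the best available model plus the flag. The full ladder is always emitted so
any other rule can be applied post hoc.

## Validation

External validation predicts the held-out test compounds and scores each by
the absolute relative error ARE = |actual − predicted|/|actual| (undefined
at actual = 0), with an overall pass when every ARE is within the threshold
(default 0.10). The report also carries the squared experimental/predicted
correlation and the test-set Q² analogue 1 − Σ(e − p)²/Σ(e − ē)².

The two-fold cross-validation scheme chains: role-based split → per-class
descriptor categorization → per-descriptor odds-ratio screen → ladder fit on
the training subset → selection of the ladder candidate with the lowest
*mean test ARE*. Model consistency is summarised by the overall-F p-value of
the selected model on the training set; this realisation of the p < 0.05
consistency check, like the odds-ratio construction below, is a
reconstruction where the original procedure is underspecified. Descriptor
numbering for the screen uses a seeded pseudo-random generator rather than
an external randomness service, so reports are reproducible; the numbering
is recorded and never affects fitting.

The odds-ratio screen dichotomizes each descriptor and the response at their
medians ("high" = strictly above), applies the Haldane–Anscombe +0.5
correction to the 2×2 counts and reports (a·d)/(b·c). It is the minimal
deterministic realisation of an otherwise undefined step, is labelled as
such, and never gates the search.

## The embedded uptake table

The per-polymorph response fixture (17 competing substrates + the
Mitoxantrone control as the 18 training sets; 7 test substrates; controls
23.71 / 27.43 / 25.92 for 482R / 482G / 482T) is stored verbatim. Percents
are recomputed as round-half-up(100·raw/control) and compared at ±1 integer
point (raw rates carry two decimals); exactly three printed cells disagree
beyond that — FumitremorginC 482R (printed 305, recomputed 113), Caffeine
482T (140 vs 179) and Epinephrine 482T (115 vs 96) — and these carry an
`inconsistent` flag instead of being corrected. Raw rates are stored
unit-agnostically, since the printed header and text disagree on units and
only ratios are used downstream. Ketoconazole appears in both subsets and
its test-set row gets the id `ketoconazole_test` to keep ids unique. The
26-descriptor reference taxonomy contains two distinct "ESP-Max net atomic
charge" entries in its quantum-chemical block; the second is named
"ESP-Max net atomic charge 2", as in the fitted-model listings. One summary
table labels a row "482C" where 482R is evidently meant; the fixture keeps
the standard polymorph names.

## Synthetic data

`SyntheticSpec` defaults encode the study shape: 18 training + 7 test
compounds; 40 descriptors split over the six classes (8/6/5/5/4/12);
within-class equicorrelation 0.3 (same-class descriptors tend to covary)
with independent classes and standard-normal marginals; a 4-term support
echoing the small fitted models — one dominant positive coefficient (+6.0),
one negative (−3.0), two smaller positives (+2.5, +1.5) — on an intercept of
200 (a percent-of-control-like scale); Gaussian noise at 5% of the noiseless
signal SD (`noise_frac=0.05`; an absolute `noise_sd` may be given instead).
Two near-duplicate columns (source + N(0, 0.03²), |r| > 0.99), two constant
columns and two columns with one missing training cell are planted on
non-support columns so that the preselection report can be checked against
the plant exactly. A `scale_mix` option multiplies columns by log-uniform
factors in [1e-3, 1e3] to exercise scale equivariance, since real descriptor
tables mix units wildly.

What the generator does *not* emulate: real descriptors are not Gaussian
(counts, bounded fractions, heavy-tailed energies), their correlation is not
block-equicorrelated, responses are not exactly linear, and biological
replicates add structured (non-iid) error. Passing recovery tests therefore
demonstrate correctness of the machinery under the stated statistical
assumptions, not predictive validity on laboratory data.

`recovery_experiment` chains generate → preselect → search → external
validation per replicate (replicate r reseeds at `seed + r`) and reports the
exact-support recovery rate, coefficient RMSE on recovered fits, mean test
ARE, the mean R² − Q² gap and the count of Q² > R² violations (none are
expected, since PRESS ≥ RSS). At the default conditions the recovery rate
measured by `scripts/acceptance.py` is ≈ 98% over 200 replicates; the
simulation sizes there (200 replicates; 12 × 8 instances for the exhaustive
oracle) are the package's standard desk-scale settings.

## Known limitations

* The printed F statistics of the original fitted models are inconsistent
  with their own N, k and R² (e.g. R² = 0.9740, N = 18, k = 4 implies
  F ≈ 122, not 56.17), and figure captions disagree with the tables; the
  package uses the standard overall-F formula and makes no attempt to
  reproduce those numbers. Whether the printed s² uses N − k − 1 or N is
  likewise unstated; N − k − 1 is used.
* The original descriptor values are not published, so the fitted
  coefficients of the reference models cannot be reproduced, only the
  machinery that produces such models.
* No variance-inflation, LASSO, simulated-annealing or genetic search
  alternatives; no y-scrambling, bootstrap validation or applicability
  domain — all outside the scope of this workflow.
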