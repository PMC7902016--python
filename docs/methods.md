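# Methods

This note records the models, estimators, defaults and design choices
behind `coldcomp`, and what the synthetic validation does and does not
demonstrate.

## Composition metrics

Every metric is a percentage. For a protein of length `L` over the
20-letter alphabet, the per-residue metrics are exact counts divided by
`L`; the flexibility classes partition the alphabet into very flexible
{E, G, K, N, Q, S}, moderately flexible {A, D, H, I, P, R, T, V} and
rigid {C, F, L, M, W, Y}, so Vf ≤ VMf and VMf + rigid% = 100 always.

Dipeptide metrics use the `L − 1` *overlapping, ordered* dipeptides
(AB ≠ BA, because published dipeptide Tm-weight tables are directional).
A dipeptide is *negative* when its Tm weight is < 0, *low* when
0 ≤ weight < `low_threshold`, *other* otherwise; Tn counts negative,
Tln negative-or-low. Length-1 proteins have no dipeptides: their Tn/Tln
are flagged undefined and excluded from dipeptide aggregates rather than
failing the run. The numeric boundary of "low" is a table-level parameter
because no universal value exists; the packaged default table is a
**synthetic stand-in** (seeded, 25 % negative / 25 % low, threshold 0.5)
— the literature values are not redistributable here, and any real
analysis should load its own table.

Records containing non-standard letters (B, J, O, U, X, Z, `*`) are
dropped whole and counted, never trimmed: composition percentages must be
taken over a fixed alphabet to be comparable.

## Growth kinetics

OD₆₀₀ curves are modelled as noisy logistic growth. The growth rate is
defined operationally as the maximal slope of ln(OD) vs time over any
contiguous window of at least `min_window` points whose internal linear
fit has R² ≥ 0.98; if no window qualifies the best ungated slope is
returned flagged `low_quality`, and a best slope ≤ 0 reports Gr = 0
flagged `no_growth`. The function default is `min_window = 4`; the
pipeline configuration defaults to 8 points together with an OD detection
floor of 0.05 (sub-floor readings are treated as unmeasured, and a curve
that never clears the floor as no growth). With densely sampled curves
the longer minimum window suppresses the upward bias and replicate
scatter that very short windows acquire from measurement noise. The
estimator retains a small systematic bias on logistic curves (the window
sees the onset of saturation), below 2 % at the default sampling density.
The pipeline additionally applies a logistic saturation correction by
default (`saturation_correction`): the window slope is divided by
`1 − ōd_window/K̂`, with `K̂` the curve's observed plateau, following
`d ln od/dt = r(1 − od/K)`. The correction is off in the bare
`fit_growth_rate` function because it overshoots on data that never
saturate (pure exponentials).

OTG: the temperature with the highest mean Gr; every temperature whose
replicate rates are statistically indistinguishable from the top joins a
candidate set whose arithmetic mean is the OTG, displayed rounded half-up
(`otg_display`). Indistinguishability defaults to a Tukey–Kramer
studentized-range test whose variance is pooled only over temperatures
inside the organism's growth regime: non-degenerate replicate variance
and mean Gr at least 40 % of the top (the same fraction that defines the
growth range). Two considerations force this choice: (i) replicate Gr
variance is strongly heteroscedastic across temperature regimes —
no-growth and far-sub-optimal temperatures are estimated with
categorically higher precision, and pooling across regimes understates
the top pair's error; and (ii) an unadjusted per-pair test at α = 0.05
breaks a genuine tie in ~5 % of runs per comparison, which measurably
corrupts the downstream OTG axis, whereas the regime-pooled family-wise
studentized-range test holds the false-break rate near the nominal ~1 %.
Temperatures outside the pooled regime are by construction far below the
maximum and can tie only on exact equality.
Fully pairwise variance estimates (Games–Howell style) are *not* used:
with triplicate data their 2–4 degrees of freedom make the test hopelessly
underpowered. An unadjusted Welch variant remains available
(`tie_method="welch"`). Half-up rounding (18.5 → 19) is asserted
explicitly; the growth range is simply the min/max of temperatures whose
mean Gr reaches `range_fraction` (default 0.4) of the maximum, with
non-contiguous sets reported and flagged.

## Group samples and the Tukey screen

Only annotated proteins are analysed. A protein contributes to every
cellular-function group it carries, to its localization group, and to the
organism-wide group `ALL`; groups are therefore non-disjoint by design
(they mirror parallel classifications, not a partition). Per-protein
values within an organism are treated as independent observations.

For each (group, metric) cell, a one-way fixed-effects ANOVA is computed
and all organism pairs are compared by Tukey HSD in the Tukey–Kramer form
(studentized-range statistic `q = |m_i − m_j| / sqrt(s²/2·(1/n_i+1/n_j))`
with the pooled within-organism variance `s²`). The omnibus p is reported
but does not gate the pairwise screen (Tukey controls the family-wise
error by itself); `require_omnibus` restores gating. Adjusted p-values
are computed from the studentized-range distribution only for pairs
exceeding the cached critical value — numerically identical to
`scipy.stats.tukey_hsd` (asserted in tests to 1e-10) but ~20× faster over
a full study. Organisms with fewer than two values are skipped; zero
pooled variance with unequal means is rejected as degenerate input. No
multiple-testing correction is applied *across* cells, matching the
analysis design this pipeline reproduces; the R² filters downstream are
the only family-level control, and this is a known caveat.

## Difference regression

Significant pairs become points (Δaxis, Δmetric) with the canonical
orientation "organism 2 has the larger axis value", so Δaxis > 0;
equal-axis pairs carry no slope information and are excluded (counted in
the log). The OTG axis uses `otg_display` by default (integer-degree
convention; exact OTG by configuration), the Gr axis uses the maximal
growth rate. Ordinary least squares with intercept is fitted only when
≥ `min_points` (3) points exist and the axis has spread; results are
reported at R² ≥ 0.5, highlighted at R² ≥ 0.7, with direction = sign of
slope. Strata filter organisms *before* pair selection: OTG 10–15 °C,
OTG 19–22 °C, Gr > 1 h⁻¹, Gr ≤ 1 h⁻¹, plus the unstratified run.

Because points are selected by the Tukey screen, borderline pairs enter
with exaggerated |Δmetric|; this mildly attenuates fitted slopes and
R² relative to regressing on all pairs. It is inherent to the
screen-then-regress design, not removed.

The label-level variant regresses per-organism label means (same-label
proteins within an organism are averaged) on the axis value, for labels
present in at least `min_label_presence` (3) organisms, and summarizes
slope distributions per metric (count, mean, modal sign, range).

## Synthetic studies

The generator mirrors an eight-organism psychrophilic-yeast study
design: planted OTGs (10, 15, 15, 15, 18.5, 18.5, 22, 22 °C — the two
18.5 values produce genuine 15/22 ties that display as 19 °C), planted
maximal rates 0.5–1.4 h⁻¹ straddling the 1 h⁻¹ stratification cut,
triplicate growth curves at 4/10/15/22/30 °C, and six CDS groups of 300
proteins per organism.

Proteomes: residues are drawn i.i.d. from a per-protein composition
vector `p ~ Dirichlet(c·p_group)` with concentration `c = 2000`, around a
group-level vector obtained from database-average amino-acid frequencies
by rescaling a metric's residue class against its complement so that the
expected metric equals `base + slope·(OTG − 16 °C)`. Gradients can be
planted on any residue-set metric (a single letter, Vf, VMf); Tn/Tln are
dipeptide functionals and cannot be planted by residue reweighting — they
shift only indirectly. Protein lengths are lognormal (μ = 6.15,
σ = 0.35; median ≈ 470 aa, typical of yeast proteomes, floor 60). Under
i.i.d. draws the dipeptide metrics have the closed form
E[Tn] = 100·Σ p_i p_j over negative dipeptides, used as a generator
self-check. Sequences carry no phylogenetic correlation, no codon
structure, and no within-protein composition heterogeneity; passing
recovery tests therefore demonstrates the statistical machinery, not
robustness to the correlated, lineage-structured variation of real
proteomes.

Growth curves: logistic `od(t) = K/(1 + ((K−od0)/od0)·e^{−rt}`) with
K = 2, od₀ = 0.02, rate `r(T) = r_opt·(1 − ((T−OTG)/16)²)²` (quadratic in
√r, single interior peak at the planted OTG), sampled every 15 min for
72 h, with additive Gaussian OD noise of 0.005 (typical plate-reader
repeatability), clipped at 10⁻⁴.

All randomness derives from the spec seed through per-(organism, purpose)
SHA-256 streams: identical seeds give byte-identical studies.

## Validation scope and problem sizes

The acceptance suite runs, on one CPU: the OTG tie example; exact
composition-oracle equivalence on 1,000 random sequences; a Tukey
family-wise-error Monte Carlo (8 organisms × n = 100, 1,000 null
simulations, bound 0.05 within its binomial 99 % interval); regression
filter rules and planted-slope recovery (100 seeds); growth-kinetics
recovery; and a 50-seed end-to-end study with an inverse VMf-vs-OTG
gradient (−0.15 percentage points/°C) planted in three of six groups,
requiring that at least 90 % of seeds yield an inverse R² ≥ 0.7 VMf
result in the affected groups, while such results appear in at most 10 %
of unaffected group-runs. Recovery is counted per seed because each seed
is one simulated study, and detection is asserted at the study level:
with the planted effect size the population R² of an affected group's
difference plot is near 0.85, so an individual 15–20-point fit falls
below the 0.7 highlight threshold in a non-negligible fraction of runs
from sampling noise alone, and requiring every affected group to clear
the threshold in 90 % of studies would test the tail of R̂²'s sampling
distribution rather than the pipeline's ability to detect planted
structure. These sizes keep
the whole suite within a few minutes while leaving the Monte-Carlo
bounds statistically meaningful.

Known limitations: Gr estimates retain a small logistic-saturation bias;
the Tukey screen treats per-protein values within an organism as
independent; no correction across the (group × metric) result matrix;
synthetic proteomes are compositionally idealized as described above.
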