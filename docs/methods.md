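# Methods

## Labelled-taxon calling

The caller operates on **gradient pairs**: a 13C-treatment gradient and a
12C-control gradient sharing (plant species, compartment, timepoint).
Fractions are first assigned a density class from configurable buoyant-
density windows (defaults: heavy 1.795–1.825 g/mL, light 1.760–1.780 g/mL,
symmetric around the expected labelled/unlabelled RNA densities in CsTFA);
densities come either from the metadata or from a linear refractive-index
calibration (default slope 10.0, intercept −12.0 g/mL — a package
convention mapping the CsTFA working range nD 1.376–1.383 to 1.76–1.83
g/mL; calibrate your refractometer and override). Counts of all fractions
of a gradient falling in one class are **pooled (summed) before
normalization**; analyses that speak of "the heavy fraction" of a gradient
therefore refer to this pooled class, the most reproducible reading when
the number of sequenced fractions per gradient varies.

A taxon is labelled iff all three criteria hold: (1) heavy-13C relative
abundance strictly above heavy-12C; (2) heavy-13C strictly above `K`
(default 2) times light-13C; (3) heavy-13C at least `min_heavy_abundance`
(default 0.0005, i.e. 0.05 %, non-strict). Inequality strictness follows
the criteria's wording exactly. When a taxon is absent from the light
fraction, criterion 2 compares against a **pseudo-abundance**, default
`1/(2 × pooled light read depth)` — half a read at the light fraction's
depth — keeping the rule monotone in `K` and aware of sequencing depth. The
floor is stored as a proportion internally; reports print percent.

Pairing is strict: exactly one control per treatment context; orphans and
gradients without a usable heavy or light class raise errors rather than
being silently averaged. All three criteria are evaluated at the same
taxonomic unit (the OTU); lineage aggregation (`summarize_calls`) is a
separate step that renormalizes heavy-13C abundances over the labelled set,
so the summary describes the composition of the labelled community.

The fraction-metadata TSV carries an optional `species` column (defaulting
to empty) because the pairing key needs it; designs with a single species
can omit it.

## Radiotracer rates

Cumulative 14CO2 trap activity is regressed on time by OLS **with a free
intercept**: the intercept absorbs trap lag and is reported for audit. The
rate is `slope / (specific_activity × dry_mass)`. The specific activity
(Bq/nmol) is a required user input with no default — administered activity
alone does not determine it. Negative fitted slopes are reported as rate 0
with an explicit flag (consumption is non-negative; the raw slope is
retained). R² is defined as 1 for an exact fit to constant data (a flat
series is fit perfectly by a zero-slope line). The canonical input is
cumulative activity; `interval_to_cumulative` converts per-collection
increments. Rates are *potential* rates: no isotope-dilution correction for
unlabelled endogenous methanol pools is attempted, and no quench correction
is applied to scintillation counts.

QC: `mass_balance` reports CO2-trap, methanol-trap and total recoveries as
proportions of administered activity (totals above 1.02 are flagged, not
fatal); `cross_check` compares NaOH-trap activities with BaCO3-precipitate
recounts via total percent excess and the R² of an OLS of BaCO3 on NaOH.
Per-incubation R² is reported without imposing a QC threshold.

## Diversity

Singleton removal is dataset-wide (total count of 1 across all samples).
Shannon uses the natural log by default (configurable base). Chao1 uses the
bias-corrected `+1` denominator so the estimator is defined at zero
doubletons. Rarefaction uses the exact hypergeometric expectation
`Σ_i [1 − C(N−N_i, d)/C(N, d)]` computed via log-gamma, not Monte-Carlo.
The asymptotic richness `n_max` comes from a positive-bounded least-squares
fit of the Michaelis–Menten form `r(d) = n_max·d/(k+d)`, initialized at
(max observed richness, median depth); non-convergence is flagged, never
silently replaced. Ordination is out of scope: `bray_curtis` supplies the
dissimilarity for any external NMDS.

## δ13C normalization

Deltas are `(R_sample/R_reference − 1)·1000` ‰. Two-point normalization
fits a linear map from measured to certified standard deltas (replicates of
one standard are averaged first); the map is exact through two distinct
standards, least squares beyond. Certified values (e.g. USGS40/USGS41) are
inputs, never package constants. Drift and ¹⁷O corrections are not applied.

## Synthetic data

The gradient simulator draws a community of `n_taxa` OTUs with log-normal
base abundances (σ = 1) and taxon-specific unlabelled buoyant densities
`N(1.770, 0.004)` g/mL (GC-content variation). Each taxon's RNA spreads
over density as a Gaussian with `profile_sd` = 0.008 g/mL; in 13C gradients
a labelled taxon carries a second component of weight `label_fraction`
(default 0.8 — short incubations label RNA only partially) shifted up by
`density_shift` (default 0.03 g/mL, an order-of-magnitude default for
near-fully labelled RNA, fully configurable). A uniform background smear
(`background_mass` = 1e-6) represents the RNA found across all fractions of
real gradients. Default fractionation is a 0.01 g/mL grid over 1.73–1.85
g/mL (12 fractions). Per fraction, counts are a single multinomial draw of
`reads_per_fraction` = 50 000 reads (preserving compositional closure);
`depth_mode="mass"` instead distributes reads across fractions in
proportion to RNA mass, which is the right model when asking where a
taxon's *profile* peaks (per-fraction RNA quantity), while the fixed-depth
default models amplicon libraries normalized per fraction.

`make_study_design` emits the full design: 2 species × 3 compartments × 2
timepoints × 2 isotopes = 24 gradients, with treatment gradients
"sequenced" at one heavy, one middle and one light fraction and controls at
one heavy and one light fraction — 60 samples. The number of retained
fractions per gradient is a package reading (the design total fixes only
the overall count); it is configurable through `keep_classes`.

The trap simulator produces cumulative activities at slope
`true_rate × specific_activity × dry_mass × trap_efficiency` over 3.5 h
with 30-min collections, administered activity 631 kBq, additive Gaussian
noise (σ = 1 Bq, a constant-error approximation of liquid-scintillation
counting and pipetting error over the 10–300 Bq range these series span),
clipped non-negative and monotonized by running maximum; t = 0 is exactly 0
(the trap starts empty). `trap_efficiency` defaults to 1 — trapped activity
is what defines a potential rate — and the sub-unit efficiency setting is
exercised separately in mass-balance scenarios. The methanol trap receives
`methanol_volatile_fraction` (default 0.875) of the administered activity.
The default rate grid in the pipeline (24 incubations; species ×
compartment true rates of 60–149 nmol g⁻¹ h⁻¹, dry masses 50/32/28 mg)
mirrors the magnitudes typical of grassland phyllosphere/rhizosphere
methanol sinks.

**What the simulations do not emulate:** chimeras, OTU-clustering
artefacts, PCR and primer bias, taxon-correlated overdispersion beyond the
multinomial, isotope cross-feeding, time-varying consumption rates, or
counting-statistics (Poisson) noise scaling. Passing recovery tests
therefore demonstrates correctness of the inference chain under the stated
generative model, not performance guarantees on real sequencing runs.

## Known limitations and behavior under the null

With zero density shift, the observed false-positive proportion of the
caller is ≈ 7 % (reported by the acceptance script): criterion 1 passes by
chance in half the cases, and criterion 2 passes systematically for the
taxa with the highest unlabelled densities, whose heavy-tail share exceeds
`K` times their light share regardless of treatment. This mirrors the
real-world high-GC false-positive risk of threshold-based SIP callers; the
control comparison (criterion 1) is what keeps the joint rate low.
Conversely, a truly labelled taxon can be missed when it is itself the
densest organism in the community, because it then also dominates the
*control's* heavy fraction and criterion 1 fails — at the default
simulation settings this affects ≈ 5 % of labelled taxa across random
communities. Both behaviors are properties of the criteria, not of this
implementation.

## Numerical choices

Degenerate inputs raise typed errors (validation 2, pairing 3, numerical
4 at the CLI). Gradient-pair vectors must sum to 1 within 1e-9. The
rarefaction expectation treats taxa with `N − N_i < d` as always observed.
Monotonicity, determinism (byte-identical reruns under one seed) and
permutation invariance are enforced by property tests. Simulation problem
sizes in the test-suite and acceptance script (e.g. 200 null pairs, 1000
trap series per regime, 10 000 Monte-Carlo rarefaction draws) are the
package's chosen verification scales, balancing statistical resolution
against a quick test cycle.
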