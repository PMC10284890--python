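# Methods

`domphoto` implements a coupled photochemical–biological analysis of lake
dissolved organic matter (DOM): ultrahigh-resolution mass spectrometry
(FT-ICR MS) peak lists are turned into molecular formula populations,
light-induced changes in those populations are detected, and the chemistry
of the photo-produced compounds is linked to microbial respiration through
response-ratio statistics. A synthetic study generator supplies inputs with
exact ground truth so every stage can be scored without field data.

## Formula assignment

Peaks are singly charged deprotonated ions [M−H]⁻, so the neutral
monoisotopic mass is m/z + 1.00727646677 Da. For each S/N > 4 peak the full
space of CcHhOoNnSs compositions with n, s ∈ {0, 1} within a relative mass
tolerance (default 1 ppm, configurable in (0, 2]) is enumerated by solving
the hydrogen count from the residual mass balance; because one hydrogen
weighs ~1.008 Da and the window is at most ±2 ppm of ≤1000 Da, at most one
integer H count can match per (C, O, N, S) combination, so the solve-for-H
search is exhaustive. Monoisotopic masses are IUPAC/CODATA values (¹²C = 12
exactly, H 1.00782503207, O 15.99491461956, N 14.0030740048, S 31.97207100).

Candidates are then filtered to the plausibility region for natural organic
matter — 0.3 < H/C < 2.2 and O/C < 1.2 (both exclusive) and neutral mass in
[100, 800] Da (inclusive) — and disambiguated by the least-heteroatom rule:
keep the candidate with the fewest N + S atoms, break ties by smallest
absolute mass error, and reject a residual exact tie as `ambiguous`. Peaks
with no surviving candidate are reported as `no_candidate`; nothing is
silently dropped.

Two deliberate scope limits: ions are never multiply charged (standard for
negative-ESI DOM), and no isotopologue flagging or Kendrick-series filtering
is attempted. An optional replicate-consistency post-filter keeps formulas
seen in ≥ k of r replicate assignments (default 2 of 3).

### Identifiability limit of exact-mass assignment

Within the filter region the CHONS space contains near-degenerate elemental
substitutions — exchanging N+S for C₇H₂O₈ shifts the mass by only ~0.18 mDa,
S+H₁₂+O₁₃ for C₂₁ by ~0.14 mDa, N+H₆+O₁₀ for C₁₅ by ~0.83 mDa. Any formula
with such a neighbour of equal or fewer heteroatoms within the working
tolerance can never be returned by the least-heteroatom rule; at 1 ppm this
affects roughly half the space above ~300 Da. This is a property of
exact-mass assignment itself, not of this implementation.

## Molecular indices and compound classes

For each assigned formula:

* DBE = 1 + (2C − H + N)/2 — rings plus double bonds;
* NOSC = 4 − (4C + H − 3N − 2O − 2S)/C — mean carbon oxidation state,
  bounded in [−4, 4];
* AI_mod = (1 + C − O/2 − S − (N + H)/2) / (C − O/2 − N − S) — the modified
  aromaticity index, a conservative lower bound on aromatic character that
  treats half the oxygen as carbonyl-like. When the numerator or denominator
  is non-positive the index is undefined and reported as 0 with a flag
  (`undefined_clamped_to_0`); the rare arithmetic value above 1 is returned
  as computed and flagged (`above_1`) rather than hidden.

Classes are assigned in precedence order (most aromatic wins):
CA (combustion-derived polycyclic aromatics, AI_mod > 0.66);
Pol (vascular-plant polyphenols, 0.50 < AI_mod ≤ 0.66);
Uns (highly unsaturated/phenolic, AI_mod ≤ 0.50 and H/C < 1.5);
Ali (aliphatics, 1.5 ≤ H/C ≤ 2.0, boundaries inclusive);
the residual 2.0 < H/C < 2.2 band is labelled Other and excluded from the
four-class ratios (Uns/Ali, Pol/Ali, CA/Ali). The precedence resolves the
rare overlap where AI_mod > 0.5 coexists with H/C ≥ 1.5.

Note that H/C < 2.2 admits H > 2C + 2 + N, for which DBE is negative; such
valence-impossible compositions can only land in the Other band. No extra
valence rule is imposed, keeping the enumeration contract exact.

Sample summaries report count, mean and median of DBE, NOSC, AI_mod and H/C
(unweighted by default; intensity-weighted on request) and class shares
(relative abundances, intensity-weighted under the `intensity` option,
count fractions otherwise; shares always sum to 1 including Other). Both
estimators are exposed because per-sample "average" indices are reported
both ways in the literature.

## Optical indices

Absorbance is stored decadic, exactly as a spectrophotometer reports it;
the Napierian conversion happens only inside the index functions:

* a₍λ₎ = 2.303 · A(λ) / path_m (m⁻¹), linear interpolation between grid
  points; a₃₀₀ proxies the amount of chromophoric DOM.
* SUVA₂₅₄ = A(254) / (path_m · DOC) in L mg C⁻¹ m⁻¹.
* Spectral slopes S₂₇₅₋₂₉₅ and S₃₅₀₋₄₀₀ by ordinary least squares of
  ln a(λ) on λ (log-linear fit, not a nonlinear exponential fit), sign
  flipped to the conventional positive S; ≥ 5 positive-absorbance points
  are required per window. S_R = S₂₇₅₋₂₉₅ / S₃₅₀₋₄₀₀.
* BIX = I(ex 310, em 380) / I(ex 310, em 430), bilinear interpolation on the
  EEM grid.
* HIX uses the overlapping-band form: trapezoid-integrated emission
  435–480 nm over 300–445 nm at the excitation row nearest 254 nm (±2 nm),
  i.e. the Zsolnay definition rather than the H/(H+L) variant — the bands
  are implemented exactly as defined, overlap included.

EEMs are assumed scatter-corrected upstream; PARAFAC decomposition and
photon-flux-dependent absorbed-light rates are out of scope.

## Differential compound detection

A sample pair (reference vs treated: dark vs light for the photochemical
step, pre- vs post-incubation for the microbial step) is partitioned by one
of two methods.

**threshold20** — a shared formula is *produced* when both its raw-intensity
ratio I_t/I_r and its total-normalised relative-intensity ratio exceed
1 + f (default f = 0.20), and *degraded* when both fall below 1/(1 + f).
Formulas present in only one sample are produced/degraded by presence. Two
design choices deserve note. First, the dual condition (raw AND normalised)
guards against total-signal drift between runs: an intensity change that
disappears after total normalisation is not trusted. Second, the
down-threshold is the reciprocal 1/(1+f) rather than a plain −20% change;
this makes "degraded" the exact mirror of "produced", so swapping the
reference and treated roles swaps the produced and degraded sets exactly —
a property the presence/absence cross-validation depends on, and one a
−20% cut would violate for ratios between 1/1.25 and 1/1.20. The threshold
is a fixed effect-size criterion, not a statistical test, so no
multiple-testing correction applies inside it.

**presence_absence** — only appearance/disappearance counts; shared
formulas are unchanged. Used to cross-validate the threshold method:
`method_concordance` reports per-set Jaccard indices and, across ≥ 3 sample
pairs, Pearson correlations of set-level chemistry between the methods.

`set_overlap_analysis` compares the AI_mod distributions of photo-produced
(PP), photo-degraded (PD) and bio-degraded (BD) compounds per lake:
set medians, pairwise two-sided Wilcoxon rank-sum tests (exact null for
small tie-free samples, normal approximation otherwise), and which pool
(PP or PD) lies closer to BD in median — the overlap diagnostic for whether
light produces or removes what microbes eat in that lake.

## Respiration and the response layer

Microbial CO₂ production after 7 or 28 days is the rise in cumulative
headspace CO₂ from day 0 (the background dissolved-inorganic-carbon signal)
minus the same rise in blank microcosms matched by incubation temperature.
Negative corrected values are retained and flagged, never clipped.

The response ratio of any quantity is RR = ln(light/dark) of treatment
means (a plain-ratio form is selectable); CO₂-RR pools the two incubation
temperatures and the replicates into each treatment mean, which is
justified when the sunlight × temperature interaction is negligible — the
three-way ANOVA exposes that term so the pooling assumption can be checked
per dataset.

DOM content is summarised as the first principal component of z-scored DOC
and DON (2×2 correlation-matrix eigendecomposition, sign fixed so the DOC
loading is positive; variance explained is (1 + |r|)/2). Associations are
quantified with standardised regression coefficients — OLS of z(y) on z(x),
whose slope equals Pearson r, with the two-sided t-test p-value (n − 2 df)
and R² = r². Factorial ANOVA uses type-II sums of squares (equal to
type-I/III on the balanced design) via statsmodels, with interaction terms
exposed under names like `treatment:temperature` (S × T) and
`treatment:lake` (S × L). Families of group comparisons are corrected with
Benjamini–Hochberg FDR at 0.05. Log transformation of responses is an
explicit per-variable flag, never applied silently.

## Synthetic study generator

The generator emulates a 10-lake × 2-light-treatment × 2-temperature ×
3-replicate incubation design end to end. All randomness descends from one
seed through per-lake substreams (`SeedSequence` spawn keys), so adding
lakes does not perturb existing lakes and written bundles are byte-identical
across runs.

* **Formula populations.** The in-filter CHONS space is enumerated
  exhaustively, classified, and sampled to a target class mix (default
  Uns 0.55, Ali 0.25, Pol 0.12, CA 0.05, Other 0.03 — a
  terrestrially-influenced lake-DOM-like composition). Planted formulas are
  restricted to the unambiguously assignable sub-space: no equal-or-fewer-
  heteroatom alternative within `isolation_ppm` = 2.2 ppm (working
  tolerance 1 ppm + 4 sd of m/z noise) of their own mass. Without this
  restriction, recovery scores would measure the identifiability limit
  described above instead of pipeline correctness. Consequently, recovery
  results say nothing about how real spectra's inherently ambiguous peaks
  are resolved — they are not resolvable by any mass-only rule.
* **Peak lists.** One peak per formula at the [M−H]⁻ m/z with Gaussian
  relative error (sd 0.3 ppm, the post-calibration accuracy class of a
  15 T instrument), lognormal intensities (μ 11.5, σ 1 in arbitrary units),
  5% of peaks drawn below the S/N = 4 cut, and a 3 ppm minimum ion spacing
  within a list (closer ions would not be resolved and would violate the
  peak-list contract). No chemical-noise peaks are emitted.
* **Light treatment.** Per class, a fraction of dark compounds is removed
  and a fraction of new compounds injected; the CA and Pol production
  fractions rise linearly along the DOM gradient u ∈ [0, 1]
  (base 0.05/0.08 + slope 0.30/0.25 · u), encoding "high-DOM lakes
  photo-produce more aromatic compounds". Shared formulas keep a common
  base intensity with 5% multiplicative noise per sample, so absent a true
  change the 20% rule calls them unchanged.
* **Bulk chemistry and optics.** DOC spans 5.69–16.76 mg L⁻¹ and DON
  0.33–1.35 mg L⁻¹ (correlated along u), matching the field ranges of the
  emulated lake set; a₃₀₀ rises 8.44–65.87 m⁻¹ along u. Spectra are
  piecewise exponentials (continuous at 320 nm) with known short/long
  slopes, so S_R is known exactly; light samples are mildly photobleached.
  EEMs are sums of three Gaussian components (two humic-like, one
  protein-like) whose balance shifts along u.
* **Respiration.** Dark 28-day production is proportional to DOC with a
  Q₁₀ = 2 temperature factor; the lake's true light/dark log response
  ratio is β · (aromatic share of its photo-produced compounds, centred)
  plus N(0, 0.15) noise, with β = 4.0 by default. A shared bottle drift
  (1.5/3.0 µmol at days 7/28) is added to samples and blanks alike so the
  blank correction is actually exercised. Day-7 values are generated but
  the response layer defaults to day 28.

Desk-scale sizes: 500 formulas per lake (vs thousands in a real spectrum)
from a 5000-formula library. 500 is the smallest size at which the
produced-compound sets (~70–80 formulas) give a stable per-lake mean AI_mod
proxy; real spectra, being an order of magnitude richer, make this proxy
correspondingly more precise.

What passing tests therefore show: the assignment, index, differential and
statistical machinery is correct on inputs whose generating process is
fully known. What they do not show: robustness to chemical noise peaks,
unresolved isobars, isotopologues, instrument drift, scatter-contaminated
EEMs, or formula populations outside the planted class mix.

## Numerical choices and degenerate inputs

* Masses are summed in a fixed element order everywhere so all code paths
  produce bit-identical values.
* Duplicate m/z within 0.1 ppm in an input peak list is an input error, not
  something to merge silently; two peaks assigned to the same formula have
  their intensities summed with a logged warning.
* Empty candidate sets, empty compound sets, single-member groups and
  zero-variance inputs raise or degrade explicitly (medians without tests,
  NaN ratios with flags) rather than producing silent numbers.
* Exact rank-sum nulls are used when both groups are ≤ 20 and tie-free.
* Text IO writes 12 significant digits, which round-trips every quantity
  used here to working precision.

## Known limitations

* Mass-only formula assignment cannot resolve the near-degenerate
  substitutions listed above; confidence in N/S-containing assignments at
  ≥ 300 Da is structurally limited at 1 ppm tolerance.
* The generator does not simulate amplicon sequencing, so the microbial
  community side of the original study design (taxa, predicted functions)
  is out of scope; the respiration link is modelled directly.
* `hix` implements the overlapping-band definition; values are therefore
  bounded above ~0.31 from below for flat spectra and are not numerically
  comparable to the H/(H+L) variant.
* The three-way ANOVA assumes a balanced (or near-balanced) design, as the
  emulated experiment provides; heavily unbalanced field designs would need
  a different sums-of-squares strategy.
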