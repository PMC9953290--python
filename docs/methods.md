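# Methods

`trophos` implements the dual stomach-content / stable-isotope workflow
used to quantify resource partitioning among co-occurring mid-trophic
("ancillary") pelagic fishes — here the community of *Scomber colias*,
*S. scombrus*, *Trachurus mediterraneus* and *T. trachurus* sampled over
three sub-basins (North, Central, South) and two depth strata (inshore
< 40 m, offshore ≥ 40 m).  This note records the models, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Diet indices

For a group of stomachs, with `n_i` the number of stomachs containing
taxon *i*, `N` stomachs examined, `c_i`/`C` the prey counts and `w_i`/`W`
the prey weights:

- fullness (%) = stomach content weight / body weight × 100; a stomach
  with fullness < 0.5% is classed empty,
- %F_i = 100 n_i / N, %N_i = 100 c_i / C, %W_i = 100 w_i / W,
- IRI_i = (%N_i + %W_i) × %F_i and %IRI_i = 100 IRI_i / Σ IRI,
- Shannon–Wiener H′ = −Σ p_i ln p_i per stomach, with p_i the count share
  (biomass share available via `basis="biomass"`).

Open choices and their resolution:

- **%N definition.** The IRI needs a numeric composition; we use the
  standard count-based form mirroring %W (the Pinkas convention).
- **%F denominator.** `N` counts *all examined* stomachs, including empty
  ones, by default; `nonempty_only=True` restricts it.  Both conventions
  appear in the diet literature.
- **Uncounted fragments.** A record with positive weight but zero count
  (unidentifiable material that was weighed, not counted) enters %N as one
  individual; the event is logged.
- **"Other" material** (scales, parasites, undigested matter) is excluded
  from diet composition and from the biomass matrices by default, and kept
  in H′ by default (it is ingested material); both are flags.

## Isotope preprocessing

δ values are per-mil deviations from PeeDee Belemnite (C) and atmospheric
N₂ (N): δ = (R_sample/R_standard − 1) × 10³.  Lipids deplete ¹³C, so δ13C
is arithmetically normalized using the bulk C/N mass ratio as a lipid
proxy:

    δ13C_corrected = δ13C_raw − 3.32 + 0.99 × C/N   (applied iff C/N > 3)

The rule is deliberately discontinuous at the gate (jump −3.32 + 2.97 =
−0.35‰): that is what the published normalization prescribes, and we
reproduce it rather than smooth it.  Records carry a `corrected_flag` so
the correction cannot be applied twice; all downstream analyses consume
the corrected value, the raw value is retained for audit.

A consequence worth knowing: when the generator is calibrated so the *raw*
δ13C–length correlation has a target R², the corrected values realize a
lower R², because the correction injects 0.99 × sd(C/N) ≈ 0.35‰ of
independent noise.  δ15N is untouched by the correction.

TL–isotope association uses the Pearson correlation with the two-sided
t-test on n − 2 df, pooled per species by default (`per_area=True` is
offered; the sampling is too unbalanced for it to be the default).

## Permutation multivariate statistics

All tests partition a dissimilarity matrix directly via the Gower-centered
matrix G = −½ J D² J (McArdle–Anderson), so no raw-data coordinates are
required.  Sums of squares for a design X are tr(H G) with H the hat
matrix of X; with a Euclidean matrix of univariate data the one-way
pseudo-F equals the classical ANOVA F exactly, which the tests verify to
1e-9.

- **Diet composition**: Bray–Curtis on log(x+1)-transformed prey biomass,
  "other" items excluded.  All-zero samples have undefined dissimilarity
  and are dropped with a warning.
- **Fullness, H′, isotope values**: Euclidean on untransformed values.

**One-way design** (area fixed, intraspecific): unrestricted permutation
of raw data.

**Nested mixed model** (species fixed, area random nested in species,
interspecific): sequential (Type I) SS on the cell design; the fixed term
is tested against the nested-term mean square per the mixed-model expected
mean squares, the nested term against the residual.  Sequential SS is the
natural choice for these unbalanced nested designs.  Permutations:

- nested term — Freedman–Lane permutation of residuals under the reduced
  (fixed-factor-only) model, G* = M G Mᵀ with M = H₁ + P(I − H₁);
- fixed term — its reduced model is the intercept alone, under which
  Freedman–Lane degenerates to unrestricted raw permutation; the
  denominator (nested) mean square is recomputed in every permutation so
  the F-ratio null distribution respects the mixed model.

p-values use (b + 1)/(m + 1) and can never be exactly zero; ties with the
observed statistic count as exceedances (conservative).  Consequence: with
small samples there is a ≈ 2·m/C(n, n/2) chance that a random permutation
reproduces the observed partition exactly, putting a floor of one tie on
extremely strong effects.  Default 9999 permutations; tests and the
acceptance script use 199–999 to keep runtimes in seconds, a resolution
choice, not a different method.

**PERMDISP** embeds samples by principal coordinates keeping real and
imaginary axes; distance to the group centroid uses the corrected formula
d² = Σ_real (u − c)² − Σ_imag (u − c)² clamped at zero (needed for
semimetric Bray–Curtis matrices), then an ANOVA F on the distances with a
label-permutation null.  Group mean dispersion reads as diet generalism
vs specialism.  Pairwise tests reuse the globally computed distances (as
`vegan::permutest.betadisper` does).  Coincident point sets yield zero
dispersion everywhere and are reported as "no test" rather than an F of
0/0.

**SIMPER** decomposes the average between-group Bray–Curtis dissimilarity
(on the same log-transformed biomass, consistent with the resemblance
matrix; raw optional) into additive per-taxon terms averaged over all
cross-group pairs; listings truncate at 60% cumulative contribution by
default.  The decomposition identity (contributions sum to the average
dissimilarity) is tested to 1e-9.

**CAP** embeds by PCoA (positive axes), then runs a linear discriminant
analysis on the first m axes, choosing m to maximize leave-one-out
allocation success over 1..min(rank, n − g, `max_m`); `max_m` defaults to
15, which bounds the LOO scan cost and is ample for these data (2–4
informative axes).  Ties in the scan prefer the smaller m.

**Pairwise comparisons** restrict the same permutation scheme to the two
levels.  No multiplicity correction is applied by default, matching
common permutational-ANOVA practice; Holm adjustment is available via
`correction="holm"`.

## Isotopic-niche geometry

All metrics operate on (δ13C_corrected, δ15N) points; areas in ‰².

- TA: convex hull area (niche extent; grows with n).
- SEA = π√(λ₁λ₂) from the sample-covariance eigenvalues; SEAc =
  SEA (n−1)/(n−2).  For bivariate normal data the standard ellipse
  contains 1 − e^(−1/2) ≈ 39.3% of points — the "core" niche.
- SEA_B: the covariance gets a vague conjugate inverse-Wishart prior
  IW(ν = 2, Ψ = 10⁻³ I); the mean-marginalized posterior IW(ν + n, Ψ + S)
  (S the centered scatter) is sampled and each draw mapped to π√det Σ.
  The posterior median concentrates on SEAc for large n.  Prior
  hyperparameters are fixed and documented because only vagueness, not a
  specific prior, is prescribed by the approach; a sensitivity check can
  rerun with Ψ scaled by 0.1× and 10×.  Fewer than 100 draws are refused
  (unstable summaries); posteriors whose 95% interval spans more than 5×
  are flagged as prior-dominated.
- Layman metrics: NR = δ15N range, CR = δ13C range, CD = mean distance to
  the centroid, MNND/SDNND = mean and SD of nearest-neighbour distances.
  SDNND uses the population (divide-by-n) convention so two points give
  SDNND = 0 exactly; sample-convention values are larger by
  √(n/(n−1)).  Nearest-neighbour ties resolve by distance value, not
  identity.
- Ellipse overlap: the intersection area of two (SEAc-scaled) standard
  ellipses by midpoint-rule grid integration over the intersection of the
  bounding boxes; the default 500×500 grid keeps the relative error of a
  moderate overlap below ~0.5%.  The overlap quantification is an explicit
  extension: the underlying study discusses "partial overlap" verbally
  without a formula.
- Groups with n < 3 report ranges only (hull/ellipse suppressed); n < 5
  is flagged as unstable, matching the sampling floor of the original
  design (≥ 5 specimens per length class when available).

## Synthetic-data generator

The raw survey data are not publicly archived, so the generator emulates
their structure; its defaults *are* the study conditions:

- **Design**: per species × area × stratum × sex cell counts transcribed
  from the published sampling table — totals 62 / 16 / 93 / 42 with
  empty-stomach rates 0/62, 6/16, 16/93, 8/42.
- **Lengths**: size classes small < 12, medium 12.1–24, large ≥ 24 cm;
  per-species class mixes reproduce the published length-frequency shapes
  (S. colias and T. trachurus small-dominated, S. scombrus 93% medium,
  T. mediterraneus medium-dominated).  TL is uniform within the band
  (only histograms are published), rounded to the 0.1 cm instrument
  resolution without letting rounding cross a class boundary.  Sexed
  adults never draw the small class; juveniles are sex-undetermined.
- **Weight**: W = aL^b with a = 0.008, b = 3.05 — generic scombrid-like
  constants; only *relative* fullness matters downstream.
- **Stomachs**: empty with the species rate; otherwise fullness uniform on
  (0.5%, 5%] of body weight (cap chosen as a realistic feeding-intensity
  ceiling), biomass shares Dirichlet(5 × profile) around the species ×
  area prey profile (concentration 5 gives realistic among-individual
  diet variation), counts multinomial with 1 + Poisson(12) individuals,
  digestion grades uniform on {0,1,2,3}.  Prey profiles are transcribed
  qualitatively from the published per-area diet descriptions (salps and
  fish larvae for S. colias, "other"-dominated S. scombrus, copepods and
  benthic prey for T. mediterraneus, *Nyctiphanes couchii* for Central
  T. trachurus, …).
- **Isotopes**: per cell, (δ13C, δ15N) = mean + slope × (TL − species mean
  TL) + bivariate normal noise; raw (uncorrected) δ13C is emitted.  Cell
  means sit inside the published ranges (δ13C −19.4…−18.2‰, δ15N
  8.2…10.9‰) with SDs ≈ 0.4‰ and ≈ 0.9–1.0‰.  Slopes with a published R²
  (δ13C: 0.39, 0.40; δ15N: 0.45, 0.56) are derived in closed form,
  slope = √(R²/(1−R²)) · sd(resid)/sd(TL), where sd(TL) comes from the
  exact mixture-of-uniforms moments of the length model (including the
  sex-conditioned class restriction) and sd(resid) pools within-cell
  noise and between-area mean spread.  Trends reported only qualitatively
  get small fixed slopes (±0.03–0.05 ‰/cm).  C/N ~ Normal(3.4, 0.35), so
  roughly 85% of samples exceed the lipid gate — representative of
  un-defatted muscle.
- **Determinism**: a single root seed feeds independent per-operation
  streams (`SeedSequence(seed, spawn_key)`), so each table regenerates
  identically regardless of call order; identical config + seed gives a
  byte-identical dataset through the CSV round trip.

What the generator does *not* emulate, hence what passing tests do not
show about real data: haul-level clustering (specimens are exchangeable
within cells), taxonomic misidentification, digestion-dependent biomass
loss (digestion grade is independent decoration), diet–isotope coupling
within individuals (stomachs and isotopes are conditionally independent
given the specimen), and any spatial structure finer than the three
areas.  Homoscedastic Gaussian noise is assumed for the within-species
isotope–TL relation, as nothing finer is published.

## Pipeline and reproducibility

`run_pipeline` runs simulate → isotope preprocessing → diet →
multivariate → niche, writing CSV tables plus a YAML manifest (seed,
permutation counts, scenario, skipped stages).  Non-fatal stage errors
(degenerate designs, empty groups) are recorded and skipped, not fatal.
Depth stratum is never a tested factor — the design is too unbalanced —
but is carried as a column.  Numbers are written with a fixed float
format, and the manifest carries no timestamps, so a fixed seed yields a
byte-identical bundle; the niche-table sub-seeds derive deterministically
from the root seed.

Problem sizes in the test and acceptance runs (199–999 permutations,
200–500 replicates for error-rate calibration, 10⁴ points for ellipse
recovery, 2·10⁵ for coverage) were chosen as the smallest sizes at which
the quantities stabilize well inside the asserted tolerances.

## Known limitations

- The nested PERMANOVA covers exactly the published two-factor design;
  there is no general linear-model PERMANOVA with covariates.
- Only Bray–Curtis and Euclidean resemblances are provided.
- CAP reports allocation success but not the trace/first-eigenvalue
  permutation tests some implementations add.
- The ellipse-overlap grid integrator is adequate for reporting overlap
  percentages, not for high-precision geometry (error ~0.5% by default).
- SIMPER reports the standard contribution table without the
  contribution/SD ratio some packages print.
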