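# Methods

## Model

The package chains four deterministic sub-models and one stochastic layer.

**Tumor allometry.** A tumor is a sphere of uniform density ρ and
cellularity κ: volume V = (π/6)(d/10)³ cm³ for diameter d in mm, mass
m = ρV, cells N = κ·m(g). Defaults ρ = 1 g/cm³ (water-equivalent; required
for a 10 cm³ tumor to weigh 10 g) and κ = 10⁸ cells/g (the low end of the
commonly quoted 10⁸–10⁹ range; solid tumors are part stroma, and published
cell counts for gram-scale breast tumors track the low end). Both are
configurable. All conversions are strictly monotone and exactly invertible,
which the test suite exercises as round-trip and cubic-scaling properties.

**cfDNA accounting.** Genome equivalents in v mL of plasma:
GE = c·v·1000/g for concentration c (ng/mL) and haploid genome mass g (pg).
Defaults c = 5 ng/mL (plasma cfDNA in individuals without cancer or with
very small cancers), v = 4 mL per 10 mL blood draw, g = 3.3 pg — the
textbook haploid genome mass, which puts a standard draw at ~6,061 genome
equivalents (~6,000 after rounding).

**Mutant-fraction scaling.** The plasma mutant fraction is linear in tumor
mass through one calibration point: f(m) = f₀·m/m₀, capped at 1, with
anchor (m₀, f₀) = (10 g, 10⁻³) from reported mutant-fraction measurements
in patients with ~10 g tumors. Mass — not diameter cubed on rounded printed
diameters — is the keying that reproduces the published extrapolated
fraction column exactly at its endpoints (1 g → 10⁻⁴, 1 mg → 10⁻⁷).
Expected copies per draw are λ(m) = GE·f(m), kept as a real-valued
expectation and never pre-rounded; rounding happens only in rendering.

**Detection.** Mutant fragments are rare and well mixed, so copies per draw
are Poisson(λε) with assay efficiency ε (default 1). Detection probability
is P(X ≥ k), default threshold k = 1. The draw (4 mL) is ~0.1% of total
plasma, so the hypergeometric finite-population correction is negligible
and deliberately not offered. An `expectation_threshold` mode implements
the deterministic reading "a draw is positive iff λε ≥ k", used for
back-of-envelope minimum-size thresholds; both the k = 1 and the 0.6-copy
targets are exercised because the published threshold discussion equates
the 0.01% fraction (λ = 0.6) with the one-copy limit, and the package
declares neither reading canonical. `min_detectable_mass` inverts the
linear model in closed form and raises an explicit infeasibility error when
the target exceeds the draw's total genome equivalents (fraction cap).

**Whole-circulation copies** use the same product at the total plasma
volume, default 3,000 mL (≈3 L adult plasma — an assumption the source
scenario never states, so every whole-circulation output carries the
assumed volume). A 1 mg tumor then has ~0.45 expected copies in the entire
circulation: order 1, consistent with the qualitative claim that a ~1 mm
tumor leaves about one copy in the whole bloodstream.

**Screening arithmetic.** Overall sensitivity is the product of maximum
panel sensitivity (default 0.80: the chance the tumor carries a mutation
the panel covers) and assay positivity given coverage (default 0.50),
giving 0.40. Expected confusion counts for a cohort of n at prevalence π:
TP = nπSe, FN = nπ(1−Se), FP = n(1−π)(1−Sp), TN = n(1−π)Sp. Two rounding
policies are always computed side by side: `nearest_integer` (half-up, the
arithmetic of worked integer cohort examples: 4/6/10/980 at n = 1,000) and
`none` (counts sum to n exactly; PPV then equals the Bayes formula to
machine precision). PPV is reported both ways because at n = 1,000 they
differ (4/14 = 28.6% vs 28.8%) yet both round to 29%. Two published
figures for this scenario are arithmetic errata — TN = 992 (the quartet
sums to 1,012) and PPV = 20% at 98% specificity (Bayes 16.8%, rounded
counts 16.7%) — and the package asserts they do *not* reproduce, reporting
computed values instead.

## Synthetic cohort simulator

`simulate_cohort` realizes the screening scenario generatively: cancer
status ~ Bernoulli(π); tumor diameter from a configurable distribution
(point mass, log-normal, or uniform — point masses at the reference table
diameters are the defaults of interest); sampled copies ~ Poisson(λ(m)ε);
panel coverage and assay positivity as independent Bernoulli layers (a
cancer screens positive only if all three succeed); false positives in
cancer-free individuals as a single Bernoulli(1−Sp), with no mechanistic
model of benign somatic mutations. One `numpy` Generator stream per run,
seed mandatory, so runs are bit-reproducible. The simulator never calls
the analytic screening formulas, so its empirical confusion matrices are
an independent check of them; tests assert agreement within three binomial
standard errors at n = 10⁵–10⁶.

What it does not emulate about real screening data: cfDNA concentration
varies person-to-person (here fixed); shedding per gram varies by tumor
type and vascularity (here one global anchor); positivity is modelled as
independent of tumor size, which is an assumption, not an observation;
there are no sequencing errors, germline contamination, or clonal
hematopoiesis — so passing tests show internal consistency of the model,
not field performance of any assay.

## Numerical choices

- Expectations and fractions are floats throughout; integer rounding
  (half-up via `floor(x + 0.5)`) exists only in the cohort-count policy and
  in text rendering.
- Poisson tails via `scipy.stats.poisson.sf(k−1, λ)`.
- Degenerate inputs: zero mass/diameter/volume propagate to zero
  everywhere; negative inputs raise `ValueError`; undefined PPV/NPV
  (empty denominator) return NaN rather than raising.
- The published reference table ships verbatim as a fixture, keyed by its
  weight column. Two printed cells are inconsistent with the spherical
  model under any keying — the 16 mg row's cell count (printed 10⁶ vs
  1.6×10⁶ from its own weight) and the 1 mg row's volume (printed
  0.0008 cm³ vs 0.001) — and are marked `known_discrepant`: the audit
  reports them as flagged failures instead of hiding or matching them.
  Golden tolerance is 15% relative for extrapolated cells (the table mixes
  rounding conventions, e.g. 62 mg printed for a 65.4 mg sphere) and 5%
  for the experimentally anchored cells.
- Copies-per-draw values below 0.1 render as "<0.1", matching the
  published column convention.

## Problem sizes

Monte Carlo checks use n = 10⁶ individuals for PPV convergence and
n = 10⁵–10⁴ for per-size detection and layer-independence checks — sizes
at which three binomial standard errors separate the tested hypotheses
comfortably while the whole suite runs in seconds.

## Limitations

No cfDNA clearance kinetics, fragment-length modelling, tumor growth or
longitudinal screening rounds, background-mutation specificity mechanism,
or non-spherical geometry. Progression-chance and mammography-sensitivity
columns in the reference table are literature annotations passed through
verbatim, never computed.
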