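# Methods

## Droplet mechanics

### Model

A gumfoot glue droplet sits at the center of a horizontal support line of
`n_f` major-ampullate fibers (diameter `d_f` µm, elastic modulus `E_f`
MPa) spanning 4800 µm between fixed supports. When the droplet is pulled
perpendicular to the line, each 2400 µm half-span deflects by an angle θ
and stretches by the factor sec θ. We treat the fibers as linearly elastic
(Hookean): each side carries tension
`n_f · (π d_f²/4) · E_f · (sec θ − 1)` along its deflected direction, and
the two sides' components perpendicular to the original line sum to the
force on the adhesive filament,

```
F(θ) = 2 · n_f · (π d_f²/4) · E_f · (sec θ − 1) · sin θ    [µN]
```

This force-resolution formula is a reconstruction from the described
geometry (the primary literature formulas are in cited prior work, not
printed); it is the standard small-deformation derivation for a point
load at the midpoint of a taut elastic line. Assumptions: fiber diameter
constant during extension (measured half-span elongations are under 4%),
negligible fiber pre-tension beyond the angle-0 state, symmetric halves.

Droplet geometry uses the parabolic-arc volume `DV = 2π·DW²·DL/15`,
flattened thickness `DV / flattened droplet area`, and adhesive core
volume `V_c = flattened core area × thickness`. The initial filament
length is the radius of the core configured as a sphere,
`(3V_c/4π)^(1/3)` — gumfoot droplets are core-rich (core ≈ 69% of droplet
volume), so extension begins at a gap of about one core radius; the
orb-web diameter convention is available as an option. True stress divides
`F` by the instantaneous cross-section `V_c / L` (volume conservation of
the core); true strain is `ln(L/L₀)`.

### Material properties

The elastic modulus is the slope of the σ–ε curve over a late-extension
window (defaults: 60–80% of time-to-pull-off for *L. hesperus*, 80–100%
for *P. tepidariorum*; secant slope for a two-point window, least squares
otherwise). Toughness is the rectangle/trapezoid sum
`Σ mean(σᵢ, σᵢ₊₁)·Δεᵢ` minus the pre-stress rectangle `σ₀·ε_total`,
deliberately the plain trapezoid rule rather than higher-order quadrature,
matching the tabulated-interval procedure; units MJ/m³ (numerically
MPa × strain). A sensitivity helper recomputes both properties with
`E_f·(1 ± δ)`; because force — hence every stress — is linear in `E_f`,
both the modulus and the toughness scale exactly by `(1 ± δ)`. (Note the
slope is *not* invariant under this scaling: a uniform force rescaling is
a vertical *stretch* of the curve, not a vertical shift.)

σ₀ is resolved from the interval-0 deflection angle; whether that angle is
the native-tension angle or the angle after the 250 µm probe advance is an
experimental-protocol ambiguity — the code simply uses whatever angle the
measurement table records at interval 0, and treats a missing (NaN) value
as σ₀ = 0 with a warning.

Angles are degrees at every interface and radians internally. The units
contract is µm / µN / MPa throughout (1 MPa·µm² = 1 µN).

### Uncertainty-aware modulus estimation

Angle measurement error propagates into stress multiplicatively with
log-sensitivity `d ln F/dθ`, which is large at small deflections (≈ 3/θ)
and bounded below by ≈ 4 rad⁻¹ near its optimum around 55–60°. The plain
window slope is therefore very noise-sensitive: for a 2° angle error the
per-point relative stress error is ≥ 14% even at the best-conditioned
angles, and a two-point slope amplifies it by the ratio of mean stress to
the window's stress increment (≈ 3.5 for the standard windows), giving
single-trial modulus errors of order 50%. `elastic_modulus_wls` fits the
slope by least squares weighted with the inverse squared propagated
stress standard error `σᵢ · (d ln F/dθ)(θᵢ) · sd_θ`; zero-deflection
points receive zero weight. Under a linear generating law this estimator
keeps the median single-trial recovery error below 10% at 2° angle noise
on the synthetic testbed. The unweighted `elastic_modulus` remains the
default analysis path.

## Synthetic droplet experiments

The simulator inverts the mechanics: it fixes a linear law
`σ = σ₀ + E·ε`, spaces true strains uniformly over the six standard
intervals up to `max_strain`, converts each strain to a droplet length and
each stress to a force, and solves `F(θ) = force` for the deflection angle
(bisection on the monotone force law; a configuration whose required
deflection reaches 89° raises an unsatisfiable-configuration error).
Gaussian noise of `angle_noise_sd` degrees is then added to the angles
(clipped to the physical range, strictly positive after the first
interval). At zero noise the mechanics pipeline recovers the generating
modulus to machine precision on any window — an identity by construction —
and the trapezoid toughness equals the analytic `E·ε_max²/2` because the
trapezoid rule is exact for linear integrands.

Default parameters: modulus 1.5 MPa and initial stress 0.1 MPa (the
measured order of magnitude for gumfoot adhesive cores); droplet
100 × 60 µm with core fraction 0.69 (the two-species average); total true
strain 1.2; two support fibers of 2.5 µm. The fiber modulus default is
800 MPa, the humid/supercontracted regime of major-ampullate silk, chosen
so that deflection angles traverse the well-conditioned 20–40° band. This
is a deliberate property of the synthetic testbed, not a claim about the
dry-fiber experiments: with ~10 GPa dry fibers the measured deflections of
real gumfoot lines stay below ~16° (half-span elongations of 0.7–3.9%),
where a 2° angle error overwhelms single-trial stress resolution — which
is why per-trial noisy recovery results on this testbed do not transfer to
the stiff-fiber regime. What the passing tests do show: the geometry,
force-resolution, curve-assembly and integration code is self-consistent
(exact noise-free inversion), and the weighted estimator is calibrated
under the declared noise model.

The simulated flattened thickness is fixed at DW/3 (a squat flattened
dome); only the product relationships among DV, thickness, areas and `V_c`
matter downstream, so this choice is a harmless normalization.

## Group comparison gate

`compare_groups` applies an Anderson–Darling normality check per group
(P ≥ 0.05 counts as normal, via the statsmodels AD implementation); two
normal groups get a two-tailed t-test, otherwise a two-sided Wilcoxon
rank-sum (the two-group Kruskal–Wallis case). The branch taken is part of
the report.

## LFQ enrichment pipeline

Confidence filters reproduce the published rule: keep a protein iff
(search score > 50 in at least one LFQ run) OR (PTM-modified in ≥ 5
Glue+Fiber samples AND PTM-search score > 50), AND LFQ > 0 in at least two
samples of *each* run. Filtering is idempotent.

Sample structure: pairwise distances `1 − Spearman ρ` over per-protein LFQ
vectors (midrank ties; a constant sample vector has undefined rank
correlation and is assigned ρ = 0), average-linkage agglomerative
clustering (linkage configurable), newick export. Outlier flagging marks
samples whose median within-type correlation falls below 0.5; flagging is
advisory and never silently drops data (the published analysis removed one
sample manually).

Per-protein statistics: the relative difference uses the symmetric-mean
denominator `(m_F − m_GF) / ((m_F + m_GF)/2)`, range [−2, 2], negative ⇔
Glue+Fiber-enriched (the cited source formula is not reproduced in the
text; this is the standard symmetric form with the sign convention fixed
to match the published figures). The enrichment test is a one-tailed
Welch t-test for mean(Glue+Fiber) > mean(Fiber) — Welch because the
reference analysis ran in R, whose `t.test` defaults to unequal variances;
the pooled-variance Student's form is available by option. Tests default
to log10(x+1)-transformed LFQ: log is the field's standard working scale
for LFQ intensities, and on the package's log-normal synthetic data the
raw scale cannot reach the planted-effect sensitivity the calibration
demands (raw-scale testing remains available via `log_transform=False`).
Zeros are treated as observed values, not imputed. Benjamini–Hochberg
adjusted p-values (statsmodels step-up) give q; "enriched" means q < 0.05.
Detection classes (both / glue_only / fiber_only) come from nonzero
detection per sample type.

Synthetic LFQ datasets are log-normal with a per-protein baseline
(mean 14, SD 1.5 on the natural-log scale), a run-2 batch offset (0.3),
a planted +3 log-unit Glue+Fiber effect for glue-labeled proteins, noise
SD 0.5, and the six-versus-five two-run design. Dropout (zeros injected
after exponentiation) is available but defaults to 0: since zeros are
deliberately treated as observed values, a single dropout zero destroys
the within-group variance estimate, and the calibration conditions assume
complete quantification. Real LFQ data have intensity-dependent
missingness, batch structure beyond a scalar shift, and correlated
proteins — none of which the generator emulates — so the calibration
results certify the pipeline's statistics under the declared model, not
performance on real spectra.

## PTM statistics

Peptides pool across samples of a type into four exclusive categories
(unmodified / glycosylated only / phosphorylated only / both). Percentages
are of the four-category total, rounded to one decimal in reports. The
2×2 enrichment tables compare a single modification against unmodified
peptides (the both-modified category is excluded), Glue+Fiber versus
Fiber; the reported odds ratio is the conditional maximum-likelihood
estimate under Fisher's noncentral hypergeometric model — the exact-test
convention of R's `fisher.test` — with the cross-product sample OR carried
alongside for transparency (they agree within 1% on tables of the
published size). The pooled-count convention reproduces the published
odds ratios exactly to their printed precision; three of the twelve
published percentage cells differ from the pooled-count computation by
0.05–0.07 points (no single denominator convention reproduces all twelve),
so those cells appear to rest on slightly different internal totals.

## Sequence properties

Hydropathy is the mean Kyte–Doolittle index (GRAVY; lower = more
hydrophilic), ambiguous residues (X/B/Z/…) skipped with a warning. The
"averaged pI" is the mean of per-residue isoelectric-point constants (the
standard free amino-acid pI table) plus one N-terminus (9.60) and one
C-terminus (2.34) value per protein — a reconstruction of the cited
averaging method, whose exact constant table is not published; it is a
descriptive composition statistic, and a Henderson–Hasselbalch
charge-neutrality solver is provided separately as a clearly different
alternative. Termini contribute once per protein record; partial
transcripts in a cluster are treated as independent records.

The Wilcoxon rank-sum test uses midranks, R's W convention (rank sum of x
minus n(n+1)/2), exact enumeration of all C(n+m, n) rank assignments for
n+m ≤ 12, and a tie-corrected continuity-corrected normal approximation
otherwise. Gland expression percentages are TPM shares summing to 100.
The Possible-Glue classification is the published disjunction: enriched at
q < 0.05, OR modified in all Glue+Fiber samples, OR aggregate-gland
expression-enriched — the last flag is consumed as an input column because
the differential-expression analysis behind it is an external tool and out
of scope here.

## Numerical choices

- Deflection solving: Brent bisection on [0°, 89°], xtol 1e-12.
- Trapezoid (not higher-order) integration for toughness, by design.
- Window selection uses interval fractions with 1e-12 tolerance.
- Modulus windows with > 2 points use least squares; exactly 2 use the
  secant slope.
- Degenerate zero-variance t-tests return p = 1; undefined relative
  difference (both means zero) raises.
- BH adjustment via the statsmodels step-up; verified against a
  brute-force oracle in tests.
- Seeds: every generator takes an explicit integer seed
  (`numpy.random.default_rng`); the CLI derives per-droplet seeds as
  `seed·1000 + i`.

## Problem sizes

The test suite and the acceptance script use 100 droplet replicates for
noisy recovery, 20 null + 5 planted LFQ datasets of 200 proteins × 11
samples for calibration, toughness oracles on 2001–4001-point curves, and
exact rank-sum enumeration up to n+m = 12; the whole suite runs in well
under a minute on one CPU.

## Known limitations

- The force model is a reconstruction; any systematic deviation of real
  fibers from Hookean behavior (viscoelasticity, pre-tension, slack) is
  not modeled.
- The stress–strain law of real adhesive is concave; the simulator's
  linear law is a testbed for recovery, not a constitutive model.
- The published species-level moduli and toughness values cannot be
  recomputed here because the raw droplet measurements live in videos and
  supplementary material; the mechanics path is validated by synthetic
  inversion and analytic oracles instead.
- No missing-value imputation, no protein inference from peptides, no raw
  spectrum processing, no differential expression (external tools).
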