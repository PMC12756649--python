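# Methods

`hircus` implements a pedigree-based genetic evaluation for early growth
traits in dairy goats in which the additive genetic variance is partitioned
into an autosomal and an X-chromosomal component, alongside maternal genetic
and maternal permanent environmental effects.  This note describes the
model, the numerical machinery, the synthetic-herd generator used for
validation, and the design choices made where more than one defensible
option existed.

## The animal model

For trait *i* the observation vector is

    y_i = X_i b_i + Z_a,i a_i + Z_s,i s_i + Z_m,i m_i + Z_pe,i pe_i + e_i

with fixed effects *b* (sex, birth year, birth month, birth type, dam age,
parity — whichever the screening stage admits), direct autosomal additive
effects *a*, direct X-linked additive effects *s*, maternal additive
effects *m* (attached to the dam of the record), maternal permanent
environmental effects *pe* (i.i.d. over dams) and residuals *e*.  Across
traits the random effects are

    a ~ MVN(0, Σa ⊗ A),  s ~ MVN(0, Σs ⊗ S),  m ~ MVN(0, Σm ⊗ A),
    pe ~ MVN(0, Σpe ⊗ I), e ~ MVN(0, Σe ⊗ I per record),

where A is the numerator relationship matrix and S its X-chromosomal
analogue.  Records with missing traits contribute a residual block equal to
Σe restricted to the observed subset (missing-at-random).  The model menu
mirrors the usual sensitivity ladder: the full structure (`model1`), the
structure without the X-linked term (`model2`), without maternal terms
(`model3`), and with a free direct–maternal covariance (`model4`, in which
the a- and m-blocks merge into one (t_a+t_m)-dimensional block).

## The X-chromosomal relationship matrix

S follows the gametic (Fernando–Grossman) parameterisation with no
dosage-compensation multiplier: each X gamete carries additive value with
base variance σs²/2; a female's X breeding value is the sum of her paternal
gamete (her sire's whole X, transmitted intact) and her maternal gamete; a
male's is his single maternal gamete.  Hence base females have S_ii = 1,
base males S_ii = ½, and σs² is the **base-population female** X-linked
variance.  The recursion is

    female i:  x_i = x_sire + ½ x_dam + φ_i
    male i:    x_i =          ½ x_dam + φ_i

with Mendelian-sampling variances d_i = ¼(1 − Fx_dam) when the dam is known
(the sire–dam relationship cancels out of the female recursion), ¾ − ¼
Fx_dam for a dam-only female, ½ for a sire-only female or dam-unknown male,
and 1 for a founder female.  Fx is the X-linked inbreeding of a female,
which on this scale equals S(sire, dam) — *not* half of it, because a
female's paternal gamete is her sire's X without sampling.  Both formulas
were validated against a Monte-Carlo gene-dropping oracle (allelic descent
with hemizygous males) before being trusted; the oracle remains in the
package as `gene_drop_oracle` and in the test suite.  S⁻¹ is assembled
sparsely as (I − M)' D⁻¹ (I − M), exactly parallel to Henderson's rules for
A⁻¹ with inbreeding.

## Restricted likelihood and AI-REML

The REML log-likelihood is evaluated through the mixed-model equations:
−2 logL = log|C| + log|G| + log|R| + y'Py + (n−p) log 2π, where C is the
coefficient matrix and y'Py = y'R⁻¹y − rhs'·sol.  This path is checked
against an independent dense-V evaluation (V = Σ Z(Σ⊗K)Z' + R) on small
fixtures for all four model structures, to 10⁻⁶.

Maximisation is AI-REML:

* the average-information matrix uses the standard working vectors
  f_k = ∂V/∂θ_k · Py, which require only current solutions;
* the score is exact; its trace terms tr(K⁻¹ C^{uu}) come from a Takahashi
  selected inverse computed on the sparse factor;
* the same traces give the classical EM update
  Σ_new = (Û K⁻¹ Û' + tr-term)/q, used as a guaranteed-ascent fallback and
  as a post-convergence check (an EM step that still improves the
  likelihood signals a premature stop and restarts the Newton loop);
* steps are Levenberg–Marquardt damped in scale-free coordinates with
  Marquardt gain-ratio control, because the AI matrix is only an
  approximation of the Hessian in the curved, near-singular regions that
  arise when several components are weakly identified;
* variances may not cross a floor of 10⁻⁸ × the trait's phenotypic
  variance; a variance pinned at the floor with non-positive score is
  frozen (its covariances held at zero) and released if its score turns
  positive; a variance can shrink by at most 99 % per iteration so
  boundaries are approached geometrically rather than jumped onto.

Convergence is declared when the likelihood gain of a full Newton step is
predicted below 10⁻³ (further iterations cannot change any reported
quantity, since parameter movements are then orders of magnitude below one
standard error), when ΔlogL < 10⁻⁸ on an undamped step, or when the last
five iterations jointly gained less than 0.05 logL units (a plateau: on
rare replicates the average-information approximation mismatches the true
curvature along a ridge and only micro-steps are accepted; riding that
ridge for hundreds of iterations would change no reported quantity
either).  Non-convergence
within `max_iter` returns the best iterate, flagged.  Standard errors are
delta-method values on the inverse AI matrix at the optimum; they are
estimates, not gospel, and their calibration is itself measured by the
parameter-recovery study below.

### Sparse linear algebra

Animal-model equations (six pedigree-structured equations per animal at the
default bivariate full model, ≈ 40 000 equations for the default herd) are
extremely sensitive to elimination order.  The package ships its own
ordering and factorisation: column groups (all effects of one animal, the
dam's permanent-environment column riding along) are peeled while their
quotient-graph degree is ≤ 2 — this removes the leaf generations — and the
remaining core is ordered by weighted minimum degree; fixed-effect hub
columns go last.  On the default herd this reproduces the fill that CHOLMOD
attains (≈1.4 M factor nonzeros for 40 k equations).  The numeric LDL' and
the Takahashi selected inverse are compiled with numba; symbolic analysis,
the value-gather map and the selected-inverse lookups are built once per
model and reused by every refactorisation, so one AI-REML iteration costs
roughly two factorisations' worth of work.

## Genetic parameters

Phenotypic variance per trait is the plain sum of that trait's fitted
variance components — the X-linked variance entering once, at its
base-female scale — plus the direct–maternal covariance when modeled.
Heritabilities are h²_a = σa²/σP², h²_s = σs²/σP², h²_m = σm²/σP², pe² =
σpe²/σP²; the "share of sex-linked variance" is σs²/(σa²+σs²)×100; genetic
correlations are element-wise correlations within each block.  Standard
errors for ratios come from the delta method on the inverse AI matrix.

## Breeding values and trends

BLUP solutions at the converged components come from the same factorised
equations; every pedigree animal (including unphenotyped ancestors)
receives autosomal, X-linked and — when modeled — maternal predicted
values.  Genetic trends are ordinary least-squares slopes of predicted
breeding values on birth date in fractional years (365.25-day years),
reported per year with standard errors.  All pedigree animals with birth
dates enter the regression; a switch restricts to phenotyped animals.

## The synthetic herd

Because the motivating data are private farm records, the package carries a
generator that emulates the study design: a closed herd with a mating ratio
of 15 does per buck, discrete generations spread over an 8-year span of
birth dates (seasonally weighted months), litters of 1/2/3 with
probabilities 0.50/0.45/0.05, weaning at 80 ± 5 days, does serving up to
two parities so dam age (1–6) and parity (1–2) vary, and roughly half of
the kids lacking a weaning record (fraction 0.53, matching the attrition
between birth and weaning counts in such datasets).  The default scenario
generates ≈ 5 300 phenotyped kids in a pedigree of ≈ 6 200 — a deliberately
scaled-down herd that keeps every validation study runnable in minutes on
one CPU while preserving the family structure that identifies the
components.

Trait architecture (BWT, WWT in kg): means 2.58 and 10.58; variance
components on the diagonal σa² = 0.007/0.126, σs² = 0.004/0.036, σm² =
0.018/0.061, σpe² = 0.001/– (BWT only), σe² = 0.108/1.430.  Between-trait
correlations are assumptions (the component sources print no covariances):
r_a = 0.13, r_s = −0.5, r_m = 0.5, r_e = 0.3, documented here and
overridable.  Fixed-effect sizes are realistic for goat kids: sex ± 0.11 kg
(BWT) and ± 0.235 kg (WWT) around the mean, year effects of amplitude
0.08/0.20 kg, month effects 0.05/0.15 kg, single/twin/triplet offsets
(+0.11, 0, −0.16) and (+0.07, 0, −0.24) kg, and small dam-age and parity
slopes.

Breeding values descend through the pedigree exactly as the estimators
assume: (a, m) jointly by the parent-average recursion with
inbreeding-corrected Mendelian-sampling variance, s gamete-by-gamete with
the sire's X copied intact to daughters.  Optional truncation selection
ranks parent candidates on a heritable merit score simulated inside the
pedigree generator; that score *is* the selected trait's autosomal value
(rescaled), with the remaining (a, m) components drawn conditionally so the
joint covariance is preserved — this keeps the selection pressure and the
analysed trait consistent, which is what produces genuine genetic trends.

What the generator does not emulate: overlapping-generation demographics,
non-random mating beyond truncation selection, pedigree errors (the
validation stage is tested on hand-built corrupted pedigrees instead),
genotype-by-environment interaction, and imprinting.  Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to violations of them.

## Validation studies

* **Oracle equivalence.**  A and S match gene-dropping covariance estimates
  (200 000 replicates) within 4 Monte-Carlo standard errors on every entry;
  A·A⁻¹ and S·S⁻¹ hit the identity within 10⁻⁸ at ~1 000 animals; the
  sparse REML likelihood matches dense-V evaluation for all four model
  structures; BLUP matches the dense GLS closed form.
* **Parameter recovery.**  Twenty replicates of the default scenario are
  simulated and refitted blind (neutral initialisation: phenotypic
  covariance split equally across terms).  Each of the 13 generating
  (co)variances should lie within 2 estimated SEs of its estimate in ≥ 90 %
  of replicates.
* **Boundary behaviour.**  With generating σs² = 0 the X-linked estimates
  collapse to the floor, the no-X structure wins on AIC in the majority of
  replicates, and the spurious term buys < 2 logL units.
* **Sensitivity.**  Omitting maternal terms inflates σ̂a² severalfold
  (direct–maternal confounding) and costs AIC; omitting the X term pushes
  its variance into the remaining components.  The sensitivity study runs
  on its own scenario with the X-linked share of the weaning-weight
  variance raised to ~13 %: at the default share (~2 %) the redistribution
  signal sits below single-replicate estimation noise at these herd sizes.
  For the same reason no claim is made that the full structure beats the
  no-X structure on AIC at scaled-down sizes — the X term's likelihood
  gain does not cover its three-parameter penalty there, although dropping
  the (much stronger) maternal terms always does cost AIC.
* **Trends.**  Slope recovery is exact on noise-free linear breeding
  values; truncation selection produces positive autosomal trend slopes.

Problem sizes used by the acceptance script: ≈ 160 animals for the
gene-dropping check, ≈ 1 000 for the inverse-identity check, 10 replicates
of the default herd for recovery and 3 for the boundary study, one
≈ 2 000-kid herd for the sensitivity pattern and one ≈ 930-kid selected
herd for the trend — sizes chosen so the full script reruns in minutes
while leaving the Monte-Carlo bounds meaningful.

## Known limitations

* The AI standard errors are asymptotic; for components near boundaries
  (σpe² at 0.001 against an SE of ~0.003) their coverage degrades, a
  well-known property of constrained REML rather than of this
  implementation.
* Model-4 fits (free direct–maternal covariance) inherit the weak
  identification the sensitivity ladder is designed to expose; expect
  large standard errors and occasional non-convergence flags.
* The simplicial LDL' targets herds of up to a few tens of thousands of
  equations; industrial-scale evaluations would want supernodal kernels.
* Univariate pre-screening fits each trait's menu separately; the package
  does not currently automate carrying the per-trait winners into a mixed
  trait-specific multivariate constraint pattern beyond the four presets.
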