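# Methods

## Scope and data model

The pipeline treats a *material library* — a set of single powdered
materials, each characterized once and roll-compacted at five hydraulic
pressures (30, 50, 70, 90, 110 bar) — and asks two questions: which
materials can be compacted to the target ribbon quality
(0.6 ≤ SF ≤ 0.8 together with TS ≥ 1 MPa), and which material attributes
drive ribbon tensile strength and solid fraction.

A material contributes: a 22-element descriptor vector; per-pressure
ribbon measurements (oil-intrusion weighings for porosity, three-point
bending for strength, three replicates each, splitting-mode codes); two
fitted compaction laws; one behavior category; and five observations of
the latent-variable model.

## Descriptor arithmetic

All descriptor formulas are elementary and implemented exactly as
defined (`descriptors.py`): Da = m/Va, Dc = m/Vc, Ie = (Dc−Da)/(Dc·Da),
IC = 100(Dc−Da)/Dc, IH = Dc/Da, tan AOR = 2h/r,
%H = 100(m3−m2)/(m2−m1), Dt = m/(V1−V2), SF_p = Da/Dt, ε_p = 1 − SF_p,
span = (D90−D10)/D50. Two conventions required a decision:

- **%Pf** (fines below 50 µm) is obtained by linear interpolation of the
  cumulative undersize curve over the histogram bin edges — deterministic
  and instrument-agnostic.
- **Homogeneity index** Iθ = F_m / (100 + Σ_{n≥1} (d_{m+n}−d_m)F_{m+n}
  + (d_m−d_{m−n})F_{m−n}) with d the bin mean diameter (µm) and F the bin
  percentage; the majority bin m is the frequency argmax with ties broken
  toward the smaller diameter. This form has the right limits: a single
  occupied bin gives Iθ = 1, and moving mass to farther bins strictly
  lowers Iθ.
- **Units**: porosities and solid fractions are stored as fractions,
  rendered as percent only at I/O; AOR is in degrees. Ie carries the
  mL/g dimension of its defining formula and is stored as the raw value.
- Measured-only descriptors (flow time, %HR, Icd, Co, Sp, Sp-co) are
  validated and passed through, never recomputed. A bulk density above
  the true density is reported with a warning, not clamped — the audit
  trail of an inconsistent measurement is preserved.

## Ribbon metrology

Porosity from oil intrusion: V_oil = (m_sat − m_dry)/ρ_oil,
V_ribbon = m_dry/ρ_true, ε = V_oil/(V_oil + V_ribbon); for single
materials ρ_true is the powder true density Dt. Tensile strength from
three-point bending: TS = 3FL/(2WT²), with the support span L = 15 mm by
default. Replicates are averaged arithmetically; the standard deviation
is kept as metadata. A ribbon sample carries a *set* of splitting modes
(it can split transversally and longitudinally at once); tallies count T
and L occurrences independently. Materials whose every pressure produced
no ribbon are flagged non-compactable and classified Category III.

## Compaction models

- **Strength–porosity** (`fit_rd`): ordinary least squares of ln TS on ε;
  k_b = −slope, TS0 = exp(intercept); R² reported in log space, the form
  in which the relation is linear and conventionally plotted. Points with
  TS ≤ 0 or missing are excluded, never imputed.
- **Strength–pressure** (`fit_power`): TS = d·P^g fitted in raw space by
  Levenberg–Marquardt (scipy `curve_fit`), initialized from the log–log
  OLS line; R² in raw space. If LM fails, the log–log coefficients are
  reported with the fit rejected.
- **Screening**: a fit is applicable iff it has ≥ 3 valid points,
  R² ≥ 0.7 (threshold configurable) and a plausible strength scale
  (TS0 ≤ 1000 MPa by default — near-constant porosity ranges can
  extrapolate to absurd zero-porosity strengths, and such fits carry no
  physical meaning). Non-monotone TS sequences are flagged as metadata
  rather than auto-rejected; they typically fail the R² screen anyway.

## RCBCS classification

Decision rule per material over its profile: Category I if any pressure
point satisfies 0.6 ≤ SF ≤ 0.8 and TS ≥ 1 MPa (boundaries inclusive);
otherwise II if any point has SF > 0.8 and TS ≥ 1 MPa; otherwise III.
Subcategory A if the qualifying criterion is met at 30–70 bar, else B.
I takes precedence over II when both could apply; a missing TS value
fails the TS ≥ 1 MPa test at that point. The classifier is verified by
exhaustive fuzzing against an independent brute-force evaluator and by a
monotonicity property (raising TS can never demote a material).

## Latent-variable model

NIPALS PLS2 with mean-centering and unit-variance scaling (ddof = 1) of
both blocks. Weight vectors are unit length with the first nonzero
element positive (deterministic sign); X and Y are both deflated by the
X-scores. Convergence tolerance is 1e-10 on the score vector with a
20000-iteration cap — the power iteration converges linearly at the
ratio of the two leading eigenvalues of XᵀYYᵀX, and near-degenerate
directions legitimately need thousands of iterations. Scores
orthogonality and the VIP normalization (mean VIP² = 1) are asserted on
every fit.

Cross-validation uses 7 venetian-blind folds dealt over a seed-shuffled
row order. Q²cum(A) = 1 − PRESS_A/SS with PRESS accumulated on
globally-scaled responses so TS (MPa) and SF (fraction) weigh equally;
RMSECV is reported per response in raw units. The number of latent
variables is the smallest A whose next-component Q² gain is below 0.01
(cap 10). Q² is computed from full-A CV predictions, not SIMCA's
per-component product rule; on the synthetic fixtures the two agree to
within the noise of fold assignment.

VIP_j = sqrt(p · Σ_a SSY_a w²_ja / Σ_a SSY_a), with SSY_a the Y sum of
squares captured by component a. Score-plot limits: the Hotelling T²
ellipse from the F-distribution for the chosen two components, and the
empirical 95th percentile of Euclidean score distances; the design space
uses the Euclidean limit (the two differ — Hotelling assumes ellipsoidal
normality, the Euclidean radius is distribution-free — and both are
exposed).

## Design space

The refined model is refit on the VIP > 1 column subset. In scaled
units the 2-LV prediction of response k at score point t = (t1, t2) is
the affine map t·c_k, so each target is a half-plane (TS ≥ 1 MPa) or a
band (0.6 ≤ SF ≤ 0.8) in the score plane; the design space is their
intersection with the 95% score-distance circle. Both a 201×201 grid
mask (spanning 1.2× the limit radius) and the analytical polygon
(half-plane/band algebra intersected with a high-resolution circle
polygon via shapely) are emitted, and every projected observation also
carries its full-A prediction so the 2-LV approximation can be audited.

A known limitation, visible on the synthetic library exactly as in real
libraries: the first two LVs do not separate Category II from Category
III materials, and the 2-LV predictions of weak (Category III) rows are
biased upward toward the data mean, so some genuinely weak materials
project near or inside the region at high pressure. Distinctly weak
observations (zero cohesion index, bottom-of-library d and TS0) do
project outside at every pressure; prediction error of the order of the
RMSECV (≈1.5 MPa for TS here) limits the fidelity of the region
boundary.

## Synthetic library

The generator (`synthetic.py`) emulates the study conditions: 81
materials (53 excipients, 28 natural-product powders), five pressures,
three replicates, category mix IA 26 / IB 3 / IIA 26 / IIB 15 / III 11
(two Category III NPPs never form ribbons; one material has cohesion
index 0). Mechanics per material:

- porosity law ε(P) = ε∞ + (ε0 − ε∞)·exp(−P/Pc) with ε0 equal to the
  powder porosity ε_p;
- strength law TS(P) = TS0·exp(−k_b·ε(P));
- noise: multiplicative lognormal on TS (σ = 0.05) and additive on SF
  (σ = 0.01) per replicate — small enough that intended categories
  survive in ≥ 90% of materials, large enough to exercise the screening;
- oil masses and bending forces are back-computed so the metrology
  recovers ε and TS exactly at zero noise.

Category identity is imposed by construction: the porosity-law
parameters are drawn from category-specific windows and TS0 is
back-solved from the binding inequality (e.g. TS at the designed
qualifying pressure, or TS(70) < 1 ≤ TS(90) for the B subcategories, or
TS(110) < 1 for Category III), keeping TS0 ∈ [0.8457, 144.8] MPa,
k_b ∈ [2.954, 32.28] and the derived pressure exponent g inside
[0.2771, 5.20] — the published library envelopes. The construction is
rejection-free and re-verified with the classifier at generation time.
Descriptors are driven by two latent factors: packing (the complement of
ε0) drives the density/flow block (Da, Dc, SF_p, IH, IC, Ie, flow time,
AOR), and plasticity (a saturating function of mid-pressure strength)
drives the cohesion index, reproducing the observed placement of TS near
Icd and opposite the bulk densities. Splitting modes are drawn with
transversal probability falling and longitudinal probability rising in
pressure, lower transversal rates for Category I.

What the generator does **not** emulate: named materials, lot-to-lot
variation, non-monotone compaction profiles, correlated replicate
errors, and instrument-specific PSD artifacts. Tests passing on this
library therefore demonstrate the correctness of the arithmetic,
fitting, classification and modeling machinery under the stated
mechanics — not the field performance of the models on any particular
real powder.

A separate fixture (`make_lvm_fixture`) provides a PLS dataset with a
known linear coefficient structure (pressure carrying the largest true
coefficient, six truly irrelevant columns) for validating VIP ranking
and variable selection against ground truth.

## Problem sizes and determinism

Default runs use the 81 × 5 library (1215 replicate rows, ≈395 modeling
observations); parameter-recovery checks use 200 materials; classifier
fuzzing uses 10⁴ random profiles; the oracle-equivalence check uses 50
random 20×6/20×2 blocks. The full pipeline is deterministic under a
fixed seed (byte-identical output tables), runs in about a second on one
CPU, and every stochastic test fixes its generator seed.
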