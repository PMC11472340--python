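# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated against, the numerical choices, and the limits of
what the tests demonstrate.

## Thermal-shift (DSF) analysis

Melt traces are modeled as a two-state unfolding transition with a linear
pre-transition baseline:

    F(T) = F0 + m·(T − T0) + ΔF / (1 + exp((Tm − T)/w))

with an optional second transition term for biphasic profiles (some
variants unfold in two steps; biphasic fits report tm < tm2 and such
variants are excluded from combined scoring by default, matching the
screening practice of dropping them after the first series — inclusion is
a configuration switch). Tm is the fitted sigmoid midpoint, not the
derivative maximum: the midpoint matches the "temperature at which half
the protein is unfolded" definition and is markedly more noise-robust.
Fits never raise on bad data; a flat trace (span below six times the
second-difference noise estimate) returns `converged=False` with reason
"no transition", and a midpoint pinned to the grid edge is likewise
reported unconverged.

The stabilization score is the piecewise map 1/2/4 for ΔTm strictly above
1/2/3 °C. The published rubric only states the positive side; the mirrored
negative scores (−1/−2/−4 below −1/−2/−3 °C) are the minimal consistent
extension and reproduce the −4 entries that appear in the packaged panel.
Boundary values take the lower bin (strict inequalities). Each
compound/variant pair is scored from the best ΔTm over the three screened
concentrations (10/30/100 µM), and scores are summed across variants.
Replicate curves are fitted individually and their Tm values averaged
(fit-then-average); averaging curves before fitting is also available but
not the default, since per-replicate fits expose outlier replicates.

## Quenching

Normalized tryptophan fluorescence is modeled as F/F0 = 1 − c/K_B, clipped
at zero, and analyzed by ordinary least squares; K_B is the magnitude of
the inverse slope (the sign is dropped by contract — quenching slopes are
negative). A slope whose 95% confidence interval covers zero yields a
"no binding" call with K_B unset. The linear model is only meaningful while
the titration stays above the clip, i.e. for K_B greater than the highest
concentration titrated; the recovery tests therefore use K_B above the
100 µM ceiling. The coverage test checks calibration of the t-based 95%
confidence interval mapped through K_B = 1/|slope| (a symmetric ±2·SE band
on K_B itself under-covers, because the reciprocal is convex).

## ITC

The single-site isotherm uses a discrete perfusion convention: each
injection of volume dV displaces an equal volume of well-mixed cell
content, so total protein (and previously formed complex) is diluted by
(1 − dV/V0) per injection while titrant accumulates. Occupied sites come
from the one-site quadratic with site concentration N·Pt, and the heat of
injection i is V0·ΔH·([PL]_i − [PL]_{i−1}(1 − dV/V0)), normalized per mole
of injectant. Under this convention the cumulative noiseless heat conserves
N·ΔH·Pt·V0 within 5% once the endpoint molar ratio exceeds 3 — displaced
complex carried its heat before leaving the cell.

The fit estimates (log K_d, ΔH, N) by trust-region least squares with the
identical forward model; log-K_d parameterization keeps the problem
conditioned across the micromolar-to-millimolar range. Initial guesses:
N from the molar ratio at half cumulative heat, ΔH from the first
injection, with decade-spaced K_d starts (0.1–100 µM) to avoid shallow
basins. Defaults follow the screening protocol: 19 injections of 2 µL of
500 µM titrant into 30 µM protein in a 200 µL cell at 20 °C (293.15 K,
configurable). A run whose largest heat is below three times the
injection-noise estimate (the scatter of the last four injections when no
estimate is supplied) is called "no binding" — the screening report never
defines its own criterion, so this conservative one is the package's.
A Wiseman c = N·Pt/K_d outside [0.5, 5000] flags the fit low-confidence
rather than rejecting it. The first injection is kept by default
(`drop_first` discards it from the residuals, common practice for the
diffusion-compromised first shot, while keeping the bookkeeping intact).
ΔG = RT·ln K_d and −TΔS = ΔG − ΔH are derived at the experiment
temperature, so ΔG = ΔH + (−TΔS) holds exactly by construction.

## Enzyme kinetics

Initial rates come from the linear window of the A300 ferrocenium-reduction
trace: rate = |slope|/(ε·ℓ·n_e), converted to µM/s. The extinction
coefficient (default 4.3 mM⁻¹cm⁻¹ at 300 nm) and electron stoichiometry
(default 2 ferrocenium ions per substrate turnover) are configuration
values to be set from the instrument calibration in use. A linear R² below
0.95 flags the rate low-confidence.

Relative activity is expressed as % of the vehicle (DMSO) control, with
significance from a one-sample t-test against 100%. A Bonferroni factor is
available for panel-wide use but the default is the uncorrected
per-compound test: the panel's own worked numbers (e.g. a 135 ± 59%
compound being non-significant at t ≈ 1.03 < 4.30 with n = 3) are computed
without correction, and a 25-fold correction would break the published
lead list. This one-sample test is a deliberate, conservative stand-in for
the original one-way ANOVA + Dunnett post-test, whose exact critical values
require multivariate-t machinery the triage decision does not need.

Inhibition modes are the general modifier Michaelis–Menten family,
v = Vmax·S/(α·Km + α′·S), with α = 1 + I/Ki and α′ = 1 for competitive,
α = α′ for noncompetitive, α = 1, α′ = 1 + I/Ki for uncompetitive, and
independent Ki, Ki′ for mixed. All series share (Km, Vmax) in the global
fit; the mode minimizes AICc (small-sample corrected AIC, appropriate for
the 30–80-point datasets here), and when the top models sit within
ΔAICc < 2 the one with fewer parameters wins, with the fixed order
none < competitive < noncompetitive < uncompetitive < mixed as the final
tie-break. Fits run in log-parameter space with multi-start Ki guesses.
The trend-based classifier (apparent Km up at constant Vmax → competitive;
Km constant, Vmax down → noncompetitive; both → mixed; 15% relative
tolerance) serves as a cross-check; on disagreement the global fit wins
and the disagreement is reported. Plain Michaelis–Menten fits use
multi-start log-space least squares so that a Km orders of magnitude below
the substrate range (the wild-type enzyme has Km ≈ 0.026 µM against a
0–1.5 mM substrate range) is still recovered from noiseless data; data
with no curvature flag Km as lower-bounded only. Dose–response uses the
four-parameter logistic; a response span under 5 percentage points (or
3× a supplied noise estimate) is "no inhibition".

## Screening stage

Docked poses are abstract typed feature points plus scores — docking
itself is out of scope, and the pipeline boundary is "poses in". A
pharmacophore point is satisfied when a feature of matching type lies
within its sphere; the default model mirrors the four mandatory restraints
(one H-bond acceptor, three hydrophobic). Pose ranking filters at
intermolecular score < −18.0 and sorts by score per heavy atom, with ties
broken by compound id so the ordering is input-order invariant.
Fingerprints default to MACCS structural keys (167-bit RDKit convention,
bit 0 unused); Tanimoto similarity and leader (sphere-exclusion)
clustering are implemented directly, with RDKit's equivalents used as
independent cross-checks in the tests. The clustering threshold (0.7) is
not published; it is configuration. Reactive/frequent-hitter patterns ship
as a small editable SMARTS file — demonstrative, not a complete PAINS/REOS
set — and flag rather than reject. logS is an ESOL-style estimate.

Apparent solubility follows the LC-MS formula
S = std_conc · (AREA_sample/AREA_std) · (INJ VOL_std/INJ VOL_sample) · DF.
Solubility–effect association uses Spearman rank correlation with a
seeded permutation p-value (10,000 permutations by default).

## Lead selection

A lead must (i) change activity by more than 25 percentage points from
control, significantly under the test above; (ii) sum per-variant
stability scores strictly above 3; (iii) show binding evidence — a numeric
ITC K_d or quenching K_B strictly below 100 µM; and (iv) retain at least
10% residual activity. The activity floor is an interpretive addition: the
stated criteria alone would admit a near-total inhibitor (2.6% residual
activity) that is a chaperone candidate in name only, and the significance
requirement likewise excludes a large-variance activity increase; together
they reproduce the published five-compound lead list from the packaged
panel. Whether the 25% criterion requires significance is configurable
(default: required). Every selection ships an audit table naming the failed
criteria of each excluded compound.

## Synthetic data

The generators emulate each assay's signal model with Gaussian,
homoscedastic noise and explicit seeds (never global state); identical
parameters and seed give bit-identical output. Default conditions mirror
the protocol: melts on a 25–60 °C grid read every 0.5 °C, the 16 quenching
concentrations (0–100 µM), the ITC protocol above, substrate from 0 to
1.5 mM (log-spaced, the standard design when Km sits far below the range
ceiling), and doses 0.25–125 µM. What they deliberately do not emulate:
baseline drift and dye artifacts in DSF, inner-filter effects in
quenching, heats of dilution and baseline-integration error in ITC,
substrate depletion in rate traces, and compound insolubility or
aggregation anywhere. Passing recovery tests therefore demonstrates
estimator correctness under the stated models, not robustness to every
real-data pathology.

Problem sizes in the test suite (200 melt curves, 50 ITC seeds per grid
point, 100 competition assays per inhibition mode at 5%-of-Vmax noise with
duplicate measurements and substrate spanning below and above Km) were
chosen to give stable statistics at interactive runtimes. The
inhibition-mode confusion study uses inhibitor levels {0, Ki/2, Ki, 2Ki};
accuracy for competitive and noncompetitive data exceeds 95% under these
conditions. Discrimination of noncompetitive from uncompetitive inhibition
degrades when nearly all substrate points lie far above Km — the two
models then differ only through a vanishing α·Km term — which is why the
confusion study samples around Km, as any mode-discrimination design
should.

## Known limitations

* The quenching model is linear, not a saturating isotherm; K_B is an
  affinity proxy valid in the linear regime only.
* One binding site per monomer; no cooperative or multi-site ITC models.
* Initial rates only; no progress-curve (integrated rate equation)
  analysis.
* The packaged panel stores summary statistics (mean ± sd, scores,
  constants), not raw traces; raw-trace analyses are exercised on
  synthetic data.
* Published kinetic values carry printed-unit ambiguities (Vmax printed as
  "µM/s^-1" is treated as µM/s; the fixture reproduces printed Km values
  without resolving their tension with the stated substrate range).
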