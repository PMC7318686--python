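# Methods

## Model and assumptions

**Model-free relaxation.** Backbone ¹⁵N R1/R2 are modeled with the
two-term Lipari–Szabo spectral density and the standard dipolar + CSA
expressions (d² = [(μ₀/4π)ħγ_Hγ_N/r³_NH]², c² = (Δσ·ω_N)²/3; R_ex adds to
R2 only). Frequencies enter as positive magnitudes (ω_N = |γ_N/γ_H|·ω_H),
the convention of standard model-free fitting software. The global
tumbling time τ_m is obtained per residue by Brent root search of the
R2/R1 ratio on τ_m ∈ [0.5, 200] ns under the rigid (τ_e = 0, R_ex = 0)
model, under which the ratio is independent of S². This assumes isotropic
overall tumbling of the protein–micelle/bicelle particle — reasonable for
quasi-spherical assemblies, and the reason a single τ_m per environment
is used downstream.

**Residue selection for τ_m.** No universal rule exists; the default
trims (a) residues flagged by the R1·R2 exchange screen
(product > median + 3·MAD, strict inequality so a zero-spread set flags
nothing) and (b) residues in the lowest decile of R2/R1, whose mobile
tails bias the rigid-ratio inversion downward. The estimate is the mean
of retained per-residue values with the standard deviation as error.

**Cross-correlated build-up.** The intensity-ratio model
ratio(T) = (3/4)·η·tanh(sT)/(s − δ·tanh(sT)), s = √(η²+δ²), is fit by
Levenberg–Marquardt least squares, weighted by the stated ratio errors.
δ (the nuisance cross-relaxation term) is fit when a series has ≥ 4
points and fixed to zero otherwise, to avoid overparameterization. The
η sign convention is η > 0 for O² > 0. Uncertainties come from seeded
Monte-Carlo resampling of the ratios (default 500 draws; the seed is
recorded on the result); when all stated errors are zero the fit residual
RMS is used as the resampling scale.

**η → O²_axis.** O²_axis = (10/9)·η·r⁶_HH /
([P₂(cosθ_axis,HH)]²·(μ₀/4π)²·γ_H⁴·ħ²·τ_m), with the environment-specific
τ_m (micelle and bicelle particles tumble at different rates, so the same
probe converts with a different τ_m in each environment). Values are
stored unclipped; conversion noise can push them slightly outside [0, 1]
and downstream stages decide how to treat that (classification clips
with a flag; entropy skips).

**Motional classes.** Class count by BIC over 1-D Gaussian mixtures
(seeded EM, 10 restarts), with a tie-break toward the larger count when
|ΔBIC| ≤ 2 — near-equal evidence is resolved toward the richer taxonomy
because a band matching a known motional class is more interpretable
than a merged one. The BIC surrogate stands in for a full Bayesian
class-count analysis and is labeled as such. Note that on the synthetic
presets (adjacent band separation ≈ 3σ, n ≈ 90) BIC often prefers 1–2
components — the pooled histogram is genuinely smooth, mirroring the
original near-tie between two and three classes — so the figure-style
analyses fix k = 3 explicitly. Centers/boundaries come from 1-D k-means
(k-means++, 50 restarts, fixed seed) on values filtered to error ≤ 0.1;
boundaries are midpoints of adjacent sorted centers. Labels low→high:
J′/J/α when k = 3 and all centers < 0.75 (the rigid ω band absent, the
membrane-protein pattern); J/α/ω when a center reaches ≥ 0.75
(soluble-protein pattern); J′/J/α/ω for k = 4; generic labels with a
warning for k = 2.

**Entropy.** The diffusion-in-a-cone mapping
S/k_B = ln[π(3 − √(1+8·O_axis))], O_axis = √O²_axis, is an
*interpretation layer*: order parameters measure motional amplitude, and
the cone model is one defensible calibration of amplitude into
orientational entropy among several. It is exact for a bond vector
diffusing uniformly in a cone, gives ln(2π) at O² = 0, decreases
strictly, and diverges to −∞ as O² → 1 — which is why out-of-domain
entries are skipped, never clipped. Alternative O²→S calibrations can be
swapped in at the `cone_entropy` seam.

**MD order parameters.** Two estimators over unit bond vectors in the
molecular frame (tumbling removed upstream): the ensemble formula
O² = (3/2)Σ w_ij⟨e_ie_j⟩² − 1/2 and the plateau (mean over the last 25%
of computed lags) of C(t) = ⟨P₂(e(τ)·e(τ+t))⟩, FFT-accelerated via the
six quadratic product series. For stationary input the two agree; both
are provided because trajectory lengths and convergence vary. Methyl-axis
O² from MD compares directly to experimental O²_axis (the axis vector is
used, so no ³-site-jump factor applies).

**Spatial statistics.** Default clustering statistic: mean within-class
pairwise distance minus overall mean pairwise distance (negative =
compact classes), with a label-permutation null (one-sided toward
clustering, +1 smoothing, default 1999 permutations). An alternative
statistic — adjusted Rand index between the class labels and a spatial
k-means partition, same permutation null — is provided; both are
reconstructions of a "k-means" spatial analysis whose exact form is not
published, and both report p-values. Rows are lexicographically sorted
before permuting so p-values do not depend on input order (rigid-body
moves leave the statistic exactly invariant and the p-value invariant to
Monte-Carlo resolution). Structures without lipid coordinates can supply
a bilayer z-slab, converted to a pseudo-cloud of grid points on the two
slab surfaces.

## Parameter defaults

| parameter | default | units | note |
|---|---|---|---|
| γ_H | 2.6752218744×10⁸ | rad s⁻¹ T⁻¹ | |
| γ_N | −2.7126×10⁷ | rad s⁻¹ T⁻¹ | |
| r_NH | 1.02 | Å | effective N–H bond length |
| r_HH (methyl) | 1.813 | Å | intra-methyl ¹H–¹H distance |
| Δσ_N | −170 | ppm | ¹⁵N CSA; conventions vary, configurable |
| θ_axis,HH | 90 | ° | ideal methyl geometry; [P₂]² = 1/4 |
| error filter | 0.1 | — | inclusive bound for class statistics |
| exchange screen k | 3 | MAD units | |
| τ_m bracket | [0.5, 200] | ns | root-search range |
| MC draws | 500 | — | per-probe error propagation |

All constants are standard values in the methyl-relaxation literature;
none is printed in a single authoritative source, so each is overridable
on `PhysicalConstants`. Temperatures are kelvin internally; the CLI
converts from °C.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* of published
membrane-protein methyl datasets: 55–90 ILVM probes; true O²_axis drawn
from a three-band mixture (J′/J/α centers 0.21/0.36/0.55 α-helical-like,
0.21/0.42/0.66 β-barrel-like; σ = 0.05; weights ≈ 1/3 each); build-up
ratios at delays 4–24 ms with noise σ = 0.01 (giving per-probe O² errors
of ~0.02, inside the experimental 0.02–0.04 band); micelle/bicelle
replicates correlated by adding a perturbation calibrated so the
truth-level R² matches the preset target (0.81 / 0.96); tumbling times
21.9/28.9 and 24.0/29.9 ns; multi-torsion (Met/Leu/Ile) fraction 3:1 in
the J′ band and 1:1 elsewhere. Backbone tables use S² ~ U(0.8, 0.9)
(rigid scaffold) with 2% rate noise and optional planted R_ex.

With equal weights the preset population mean is ≈ 0.37 (α-helical-like)
and ≈ 0.43 (β-barrel-like) rather than the 0.36 experimental ensemble
means, which reflect the real proteins' unequal band populations; the
synthetic presets fix weights at 1/3 by design and downstream tests
compare against the generator's own ground truth, not the experimental
means.

Not emulated: spectral resolution and peak overlap (no notion of the
resolvable-probe fraction), scaffold anisotropy of tumbling,
temperature-dependent band shifts, and any real structural context
(spatial datasets are Gaussian point clouds with planted or null label
structure). Passing tests therefore demonstrate correctness of the
analysis chain under the stated statistical model, not fidelity to any
particular protein.

Two noise-level facts discovered by simulation and worth knowing: the
observed micelle/bicelle R² on *fitted* sets is attenuated a few percent
below the truth-level target (r² = V²/((V+σ_f²)(V+σ_e²+σ_f²)) with
fit variance σ_f² ≈ 2×10⁻⁴), which the end-to-end checks account for;
and the R1·R2 exchange screen reliably recovers planted outliers only
when the exchange contribution exceeds the product spread induced by the
scaffold S² distribution (R_ex = 8 s⁻¹ at 25% contamination sits at the
detection edge — ~60% recovery; R_ex ≥ 12 s⁻¹ or ≤ 10% contamination
recover ≥ 80–90%).

## Problem sizes

Default analysis scales: 90 + 55 probes × 2 environments for the
end-to-end pipeline (Monte-Carlo error draws reduced to 25–200 where
only central values are asserted); 200 replicates for tumbling-time bias;
10⁶ frames for the cone-trajectory oracle (reflecting random walk in
(cos θ, φ), step sizes set for a decorrelation time of ≈ 50 frames, so a
4000-lag window sits far past equilibration); 100 repetitions × 199
permutations for null-uniformity calibration of the permutation tests.

## Known limitations

* No full per-residue model-free fitting of (S², τ_e, R_ex); only τ_m
  and the exchange screen are implemented, matching how the backbone data
  are used in this analysis.
* No CPMG dispersion fitting; the R1·R2 product is the only µs–ms probe.
* τ_m uncertainty is not propagated into per-probe O² errors (it is a
  common-mode scale affecting every probe identically).
* PDB input only (first model, altloc '' or 'A', author numbering); no
  mmCIF. Trajectory input is plain (t, x, y, z) TSV; binary trajectory
  formats are assumed converted upstream.
* The Bayesian class-count analysis is approximated by BIC on Gaussian
  mixtures; the spatial "k-means" statistic is a reconstruction.
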