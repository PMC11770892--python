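# Methods

`brainnetkit` implements a cross-scale resting-state brain-network analysis
that starts from regional tables — gray-matter volumes (GMV) per atlas
region for a structural arm, and regional BOLD time series for two
functional arms — rather than from images. All image-domain preprocessing
(segmentation, normalization, smoothing, voxelwise covariate regression) is
out of scope; the package's boundary is the 90-region AAL parcellation
table.

## Structural covariance networks

Regional GMV is residualized against age and sex by ordinary least squares,
pooling both groups in one regression so that group-specific nuisance fits
cannot inject artificial group differences. The group covariance network is
the region-by-region Pearson correlation of residualized GMV across that
group's subjects. A per-subject 90 × 90 correlation matrix cannot be formed
from one scalar per region per subject, so the group-level covariance
reading is used throughout.

Weighted networks are binarized over a sparsity grid (default 0.05–0.40 in
steps of 0.01, 36 points). The edge count at sparsity S is
round(S·n(n−1)/2), rounding half away from zero; signed weights are ranked
(strong negative covariances never enter; an absolute-value ranking is a
caller choice by passing |r|), and ties at the cutoff break toward the
lower (row, col) pair so the count is exact and deterministic. Note a
consequence: an all-ties matrix below sparsity 1 keeps only the
lexicographically first pairs, not a "uniformly thinned" complete graph.

Binary-graph metrics: clustering coefficient (2·triangles/k(k−1), zero for
degree < 2), characteristic path length (mean shortest path over *reachable*
pairs — unreachable pairs are excluded rather than imputed, a convention
that rarely binds because the minimum sparsity is chosen for connectivity),
global/local/nodal efficiency, degree, and unnormalized fractional-count
betweenness. Small-world indices Gamma (Cp ratio), Lambda (Lp ratio) and
Sigma = Gamma/Lambda are normalized by the mean of degree-preserving
double-edge-swap random networks (default 100 nulls, 10·|E| swap attempts
each). Curves over the grid are summarized threshold-free by trapezoidal
AUC.

Group inference permutes group labels: both covariance networks and all
AUCs are recomputed per permutation, and the two-tailed add-one p-value is
(1 + #{|null| ≥ |obs|})/(1 + n_perm). Nodal p-values are Benjamini–Hochberg
corrected across regions within each metric (q = 0.05). Note the add-one
floor interacts with BH: with 200 permutations the smallest attainable p
(1/201) already exceeds the rank-1 BH threshold for 20 or more regions, so
nodal FDR detection requires on the order of 1000 permutations — the
default used here.

## Multilayer temporal networks

Each subject's series is cut into sliding windows of 20 TRs with a 0.95-TR
step; fractional onsets are rounded half-up to integer volumes, which on a
210-volume series yields 201 windows. Windowed Pearson correlations with
negative entries zeroed and zero diagonal form the layers.

The multislice modularity of an assignment g is

    Q = (1/2μ) Σ_{ijs} [A_ijs − γ k_is k_js / 2m_s] δ(g_is, g_js)
      + (1/2μ) 2ω Σ_{is} δ(g_is, g_{i,s+1}),   2μ = Σ_s 2m_s + 2ωN(L−1)

with resolution γ, ordinal (adjacent-layer, uniform) interlayer coupling ω,
and empty layers contributing only coupling terms. Optimization is a
generalized Louvain: greedy single-node moves in a random visit order
(first strictly improving maximal-gain move wins, which makes runs
deterministic under a seed), followed by exact aggregation of community
masses and greedy merging of supernodes, iterated until no move or merge
remains. The local-move sweep is numba-compiled; aggregation uses a sparse
community-mass matrix because the first phase can leave thousands of small
communities at this problem size. Because the heuristic is stochastic, each
subject × (ω, γ) setting is optimized `n_repeats` times (default 50) and
switching rates and Q are averaged across repeats, not consensus-clustered.

The switching rate of node i is the fraction of the L−1 adjacent-layer
transitions at which its module changes. The parameter grid is
ω ∈ {0.5, 0.75, 1} × γ ∈ {0.9, 1, 1.1}; comparisons are performed per
setting (whether rates should additionally be averaged across settings is
not settled; per-setting is the transparent choice). Group comparison is a
per-node Welch t-test with BH-FDR across nodes.

## Spectral effective connectivity

The directed model over the six regions of interest (L.SFG, L.SMA, L.SPG,
R.SPG, R.IPL, L.THA; MNI coordinates carried as metadata) is a linear
stochastic system dx/dt = A x + v observed through a fixed canonical
double-gamma hemodynamic response (peak 6 s, undershoot 16 s, ratio 1/6)
with additive measurement noise. Off-diagonal couplings of A (in Hz) are
free; self-connections are parameterized −0.5·exp(a_ii) so they stay
negative. Endogenous fluctuations have spectrum σ_v²(f/f₀)^(−β_v) with
f₀ = 0.01 Hz.

The model-implied cross-spectral density is

    G_y(ω) = |h(ω)|² T(ω) G_v(ω) T(ω)* + σ_e² I,  T(ω) = (iωI − A)⁻¹,

where h is the closed-form Fourier transform of the double-gamma kernel.
Estimation minimizes the squared discrepancy between this prediction and a
Welch estimate of the observed cross-spectra (Hann taper, 50% overlap,
band restricted to (0, 0.1] Hz excluding the Nyquist bin), stacking real
and imaginary parts of the upper triangle, normalized by mean observed
power, with (a) a ridge pseudo-observation per off-diagonal coupling of
weight tied to the data-residual count, prior mean 0 and prior SD 0.125 Hz
(the conventional coupling prior variance of 1/64), and (b) a soft barrier
on the largest eigenvalue real part keeping the fitted system stable.
Levenberg–Marquardt with multi-start from seeded jitter; the best-objective
solution is returned with diagnostics (cost, convergence flag, stability
margin). This penalized least-squares scheme is a transparent, testable
estimator of the same directed-coupling quantity that variational
free-energy spectral schemes target; it deliberately omits posterior
covariances and Bayesian model comparison. One convention matters:
`scipy.signal.csd(x, y)` estimates E[X*Y], the conjugate of the model's
E[X_i X_j*], and is conjugated on ingestion — getting this wrong silently
transposes every estimated coupling.

Group comparison is a per-directed-edge Welch t-test on coupling strengths,
reported uncorrected at p < 0.05; tables are printed with rows as source
and columns as target regions and a zero diagonal.

## Statistics layer

Two-sample tests default to the Welch form with Satterthwaite degrees of
freedom (a pooled-variance flag exists); this is the variant consistent
with the demographic table it reproduces, e.g. the age row (t = −1.60,
df ≈ 86.5, p = 0.113) where the pooled test gives a different p. The 2×2
chi-square is implemented with and without the Yates correction; for the
sex-distribution counts (30/40 vs 23/58) these give p ≈ 0.063 and ≈ 0.092
respectively, and neither reproduces the printed 0.087 exactly — the
discrepancy is documented, not reconciled. Correlation p-values use the
exact t transform t = r√((n−2)/(1−r²)). BH-FDR wraps
`statsmodels.multipletests`. p-values are floored at 1e-300.

## Synthetic data

The generators define the study conditions and are pure functions of their
spec including the seed.

* **GMV cohorts** (defaults 70 + 81 subjects, 90 regions): a linear factor
  model with 6 contiguous-block factors (loading 0.8), per-region noise SD
  0.6, optional linear age (uniform 18–65) and sex (Bernoulli 0.5) effects,
  and a group-2 perturbation multiplying selected regions' loadings. The
  implied correlation structure is the standardized ΛΛᵀ + Ψ, recovered
  empirically at large n.
* **Modular BOLD** (defaults 90 regions, 210 volumes, TR 2 s): node series
  are √ρ·module-latent + √(1−ρ)·private noise (ρ = 0.85) plus measurement
  noise (SD 0.3), band-passed 0.01–0.08 Hz with a zero-phase FIR filter
  (forward–backward, so no phase distortion; taps capped by series length).
  Designated switch nodes advance cyclically to the next module at planted
  epochs, and the planted per-epoch assignment is returned as ground truth.
* **Coupled BOLD**: Euler–Maruyama integration of dx/dt = A x + v at TR/10
  (stable for the ≤ 2 Hz couplings exercised), a 50 s burn-in discarded,
  convolution with the double-gamma kernel at the fine step, decimation to
  TR, additive white observation noise. Decimation is deliberately plain:
  the hemodynamic kernel is the physical anti-alias filter, and the no-HRF
  configuration (used in closed-form spectrum checks) therefore shows mild
  aliasing of the Ornstein–Uhlenbeck tail at high band edges.

What the generators do *not* emulate: spatial autocorrelation and
registration error in GMV, physiological noise, motion, non-stationary
noise floors, hemodynamic variability across regions, and empirical module
sizes. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to everything real MRI
contains.

## Problem sizes and numerical choices

Simulation-based checks are sized to what the analyses need, not more:
permutation calibration runs 50 replicates of 200 permutations at 20
regions and 4 sparsity points with the null-normalized indices left out
(their random-network nulls add nothing to a calibration of the label
permutation itself); planted-switch recovery uses the full 90 × 201
multilayer size with 30 subjects per group and 10 optimizer repeats;
estimator recovery uses 3-node systems at 1000 volumes across 20 seeds.
Degenerate inputs are handled explicitly: zero-variance regions or window
nodes are zeroed with a warning, empty graphs make path length an error,
zero marginals make the chi-square an error, and permutation p-values can
never be exactly zero by the add-one rule.

## Known limitations

* The Louvain heuristic guarantees non-decreasing quality, not global
  optima; equivalence with exhaustive enumeration is verified only on small
  instances.
* The spectral estimator's ridge weighting is a fixed design choice, not a
  learned hyperparameter; very weak couplings (well below the 0.125 Hz
  prior SD) are shrunk toward zero by construction.
* The window count of 201 presumes 210 usable volumes; the scan length is
  configurable because acquisition-discard arithmetic varies across sites.
* Betweenness delegates to networkx (Brandes) and is the slowest nodal
  metric in permutation loops; restrict nodal metrics when permuting if it
  matters.
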