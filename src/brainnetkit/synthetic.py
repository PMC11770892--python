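"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators stand in for the study cohort:

* ``generate_gmv_cohort`` — two groups of regional gray-matter volumes with
  factor-structured between-region covariance, linear age and sex effects,
  and a group-specific perturbation of selected regions' factor loadings.
* ``generate_dynamic_bold`` — modular band-limited BOLD in which designated
  nodes change module membership at planted epochs, giving ground truth for
  switching-rate recovery.
* ``simulate_linear_dcm`` — BOLD generated from a known directed coupling
  matrix through the linear stochastic model and the canonical hemodynamic
  response, for effective-connectivity estimator recovery.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .spectral import DEFAULT_HRF_PARAMS, hrf_kernel

__all__ = [
    "GmvCohortSpec",
    "DynamicBoldSpec",
    "LinearDcmSpec",
    "generate_gmv_cohort",
    "generate_dynamic_bold",
    "simulate_linear_dcm",
    "region_labels",
]

#: Age range (years) and sex balance used for the simulated cohorts,
#: mirroring the recruitment window of the emulated study (adults 18-65).
AGE_RANGE = (18.0, 65.0)
SEX_PROB = 0.5


def region_labels(n_regions: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n_regions)]


def _block_loadings(n_regions: int, n_factors: int, loading: float = 0.8) -> np.ndarray:
    """Contiguous-block factor loadings: region r loads on factor r*K//N."""
    lam = np.zeros((n_regions, n_factors))
    bounds = np.linspace(0, n_regions, n_factors + 1).astype(int)
    for f in range(n_factors):
        lam[bounds[f]:bounds[f + 1], f] = loading
    return lam


# ---------------------------------------------------------------------------
# Gray-matter-volume cohorts
# ---------------------------------------------------------------------------

@dataclass
class GmvCohortSpec:
    """Factor-model specification of a two-group GMV cohort.

    Region r of subject s takes the value
    mu_r + Lambda_r . f_s + age_beta_r * age_s + sex_beta_r * sex_s + eps,
    with standard-normal factors f_s and N(0, noise_sd_r^2) noise.  Group-2
    subjects use loadings multiplied by ``perturbation_scale`` on the
    ``perturbed_regions``.
    """

    n_group1: int = 70
    n_group2: int = 81
    n_regions: int = 90
    factor_loadings: np.ndarray | None = None  # (n_regions, n_factors)
    noise_sd: float | np.ndarray = 0.6
    age_beta: float | np.ndarray = 0.0
    sex_beta: float | np.ndarray = 0.0
    region_means: float | np.ndarray = 5.0
    perturbed_regions: tuple[int, ...] = ()
    perturbation_scale: float = 1.0
    n_factors: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_group1", "n_group2", "n_regions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.factor_loadings is None:
            self.factor_loadings = _block_loadings(self.n_regions, self.n_factors)
        self.factor_loadings = np.asarray(self.factor_loadings, dtype=float)
        if self.factor_loadings.shape[0] != self.n_regions:
            raise ValueError("factor_loadings must have n_regions rows")
        if np.any(np.atleast_1d(self.noise_sd) <= 0):
            raise ValueError("noise_sd must be > 0")
        if any(r < 0 or r >= self.n_regions for r in self.perturbed_regions):
            raise ValueError("perturbed_regions must be valid region indices")


def generate_gmv_cohort(spec: GmvCohortSpec) -> pd.DataFrame:
    """Generate the cohort table: subject, group, age, sex, then one column
    per region."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_group1 + spec.n_group2
    n_regions = spec.n_regions
    lam = spec.factor_loadings
    n_factors = lam.shape[1]

    noise_sd = np.broadcast_to(np.atleast_1d(spec.noise_sd), (n_regions,))
    age_beta = np.broadcast_to(np.atleast_1d(spec.age_beta), (n_regions,))
    sex_beta = np.broadcast_to(np.atleast_1d(spec.sex_beta), (n_regions,))
    mu = np.broadcast_to(np.atleast_1d(spec.region_means), (n_regions,))

    age = rng.uniform(*AGE_RANGE, size=n_total)
    sex = rng.binomial(1, SEX_PROB, size=n_total)
    factors = rng.standard_normal((n_total, n_factors))
    eps = rng.standard_normal((n_total, n_regions)) * noise_sd

    lam2 = lam.copy()
    if spec.perturbed_regions:
        lam2[list(spec.perturbed_regions), :] *= spec.perturbation_scale
    group = np.array([1] * spec.n_group1 + [2] * spec.n_group2)
    loadings_per_subject = np.where((group == 2)[:, None, None], lam2[None], lam[None])
    signal = np.einsum("srf,sf->sr", loadings_per_subject, factors)
    gmv = mu + signal + age[:, None] * age_beta + sex[:, None] * sex_beta + eps

    df = pd.DataFrame(gmv, columns=region_labels(n_regions))
    df.insert(0, "sex", sex)
    df.insert(0, "age", age)
    df.insert(0, "group", group)
    df.insert(0, "subject", [f"S{i + 1:04d}" for i in range(n_total)])
    return df


# ---------------------------------------------------------------------------
# Modular BOLD with planted module switching
# ---------------------------------------------------------------------------

@dataclass
class DynamicBoldSpec:
    """Modular band-limited BOLD with designated switching nodes.

    Each node's raw series is sqrt(rho) times its current module's latent
    series plus sqrt(1-rho) private noise (rho = ``within_module_corr``),
    plus ``noise_sd`` measurement noise, band-pass filtered to ``band``.
    ``switch_nodes`` advance to the next module (cyclically) at each volume
    index in ``switch_epochs``; all other nodes keep their base module.
    """

    n_subjects: int = 10
    n_regions: int = 90
    n_volumes: int = 210
    tr_seconds: float = 2.0
    n_modules: int = 4
    base_modules: np.ndarray | None = None  # (n_regions,) module ids 0..M-1
    switch_nodes: tuple[int, ...] = ()
    switch_epochs: tuple[int, ...] = ()
    within_module_corr: float = 0.85
    noise_sd: float = 0.3
    band: tuple[float, float] = (0.01, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_modules is None:
            self.base_modules = np.arange(self.n_regions) * self.n_modules // self.n_regions
        self.base_modules = np.asarray(self.base_modules, dtype=int)
        self.n_modules = int(self.base_modules.max()) + 1
        if not (0 < self.within_module_corr < 1):
            raise ValueError("within_module_corr must lie in (0, 1)")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 < low < high")
        if any(n < 0 or n >= self.n_regions for n in self.switch_nodes):
            raise ValueError("switch node outside the node set")
        eps = np.asarray(self.switch_epochs)
        if eps.size and (np.any(np.diff(eps) <= 0) or eps[0] <= 0 or eps[-1] >= self.n_volumes):
            raise ValueError("switch_epochs must be strictly increasing within (0, n_volumes)")

    def module_map(self) -> np.ndarray:
        """Planted (n_epochs, n_regions) node-to-module assignment."""
        n_epochs = len(self.switch_epochs) + 1
        out = np.tile(self.base_modules, (n_epochs, 1))
        for e in range(1, n_epochs):
            for node in self.switch_nodes:
                out[e, node] = (out[e - 1, node] + 1) % self.n_modules
        return out

    def epoch_bounds(self) -> list[tuple[int, int]]:
        edges = [0, *self.switch_epochs, self.n_volumes]
        return list(zip(edges[:-1], edges[1:]))


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Zero-phase FIR band-pass along axis 0."""
    n_time = x.shape[0]
    numtaps = min(51, max(9, (n_time // 4) | 1))
    taps = sps.firwin(numtaps, band, pass_zero=False, fs=fs)
    return sps.filtfilt(taps, [1.0], x, axis=0)


def generate_dynamic_bold(spec: DynamicBoldSpec) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Generate per-subject time-series tables and the planted module map.

    Returns (list of volumes x regions DataFrames, module_map with shape
    (n_epochs, n_regions)).
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.within_module_corr
    mod_map = spec.module_map()
    bounds = spec.epoch_bounds()
    fs = 1.0 / spec.tr_seconds
    cols = region_labels(spec.n_regions)
    subjects = []
    for _ in range(spec.n_subjects):
        latents = rng.standard_normal((spec.n_volumes, spec.n_modules))
        private = rng.standard_normal((spec.n_volumes, spec.n_regions))
        x = np.empty((spec.n_volumes, spec.n_regions))
        for e, (t0, t1) in enumerate(bounds):
            assign = mod_map[e]
            x[t0:t1] = (
                np.sqrt(rho) * latents[t0:t1, assign]
                + np.sqrt(1 - rho) * private[t0:t1]
            )
        x += spec.noise_sd * rng.standard_normal(x.shape)
        x = _bandpass(x, spec.band, fs)
        subjects.append(pd.DataFrame(x, columns=cols))
    return subjects, mod_map


# ---------------------------------------------------------------------------
# BOLD from a known directed coupling matrix
# ---------------------------------------------------------------------------

@dataclass
class LinearDcmSpec:
    """Forward model for effective-connectivity recovery.

    Integrates dx/dt = A x + v (Euler-Maruyama at TR/10), convolves with the
    canonical double-gamma hemodynamic kernel, samples at TR and adds white
    observation noise.  v is Gaussian with amplitude ``fluct_amp`` and
    power-law spectral slope ``fluct_exponent`` (0 = white).
    """

    A: np.ndarray = field(default_factory=lambda: -0.5 * np.eye(3))
    fluct_amp: float = 1.0
    fluct_exponent: float = 0.0
    obs_noise_sd: float = 0.05
    hrf_params: tuple[float, float, float] | None = DEFAULT_HRF_PARAMS
    n_volumes: int = 1000
    tr_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if np.any(np.linalg.eigvals(self.A).real >= 0):
            raise ValueError("A must be stable (all eigenvalue real parts < 0)")
        if self.fluct_amp <= 0:
            raise ValueError("fluct_amp must be > 0")


def _powerlaw_noise(rng, n, beta, dt, f0):
    """Gaussian series with spectrum proportional to (f/f0)^(-beta)."""
    white = rng.standard_normal(n)
    if beta == 0:
        return white
    f = np.fft.rfftfreq(n, d=dt)
    shaping = np.ones_like(f)
    shaping[1:] = (f[1:] / f0) ** (-beta / 2)
    shaping[0] = 0.0
    spec = np.fft.rfft(white) * shaping
    x = np.fft.irfft(spec, n=n)
    return x / x.std() if x.std() > 0 else x


def simulate_linear_dcm(spec: LinearDcmSpec) -> pd.DataFrame:
    """Simulate BOLD (volumes x nodes) from a known coupling matrix."""
    rng = np.random.default_rng(spec.seed)
    n = spec.A.shape[0]
    oversample = 10
    dt = spec.tr_seconds / oversample
    burn = 50 * oversample  # discard transient from the x=0 start
    n_steps = spec.n_volumes * oversample + burn

    v = np.column_stack([
        _powerlaw_noise(rng, n_steps, spec.fluct_exponent, dt, f0=0.01)
        for _ in range(n)
    ]) * spec.fluct_amp

    x = np.zeros((n_steps, n))
    sq = np.sqrt(dt)
    for t in range(1, n_steps):
        x[t] = x[t - 1] + dt * (spec.A @ x[t - 1]) + sq * v[t]

    if spec.hrf_params is not None:
        t_kernel = np.arange(0, 32.0, dt)
        h = hrf_kernel(t_kernel, spec.hrf_params) * dt
        y = np.column_stack([np.convolve(x[:, i], h)[: n_steps] for i in range(n)])
    else:
        y = x
    y = y[burn::oversample][: spec.n_volumes]
    y = y + spec.obs_noise_sd * rng.standard_normal(y.shape)
    return pd.DataFrame(y, columns=region_labels(n))
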