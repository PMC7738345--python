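"""Seed-reproducible synthetic rice-leaf spectra, N contents and plot yields.

No public accession of the original field data exists, so this module
generates sample tables with the statistical structure the downstream
analysis assumes: four nitrogen treatments (0/50/100/150 kg/ha), leaf N
content distributed around treatment-specific means, leaf reflectance on
the 401-1000 nm grid responding to N through a chlorophyll-style mechanism
(darker visible region and a red edge shifting to longer wavelengths as N
increases), and a yield response peaking at the 100 kg/ha treatment.

The reflectance model is a stylized Gaussian-feature curve, not a
radiative-transfer model: the pipeline, not leaf optics, is the subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .grid import N_BANDS, REFLECTANCE_COLUMNS, wavelengths

__all__ = [
    "SimulationConfig",
    "generate_samples",
    "generate_yields",
    "reflectance_matrix",
    "make_nonlinear_problem",
    "make_planted_problem",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic field experiment.

    Defaults emulate the study conditions: 4 replicate plots per treatment,
    16 leaves sampled per plot (256 samples, close to the 259 of the field
    campaign), treatment N rates 0/50/100/150 kg/ha, and per-treatment leaf
    N means of 1.8/2.6/3.3/3.8 mg/g with a common 0.45 mg/g spread so the
    pooled distribution approximates the reported moments (mean ~2.90,
    range ~1.06-4.87 mg/g).
    """

    seed: int = 0
    n_plots_per_treatment: int = 4
    n_samples_per_plot: int = 16
    treatments: tuple[int, ...] = (0, 50, 100, 150)
    noise_sd: float = 0.01
    n_mean_by_treatment: tuple[float, ...] = (1.8, 2.6, 3.3, 3.8)
    n_sd: float = 0.45

    def __post_init__(self) -> None:
        if len(self.treatments) == 0:
            raise ValueError("at least one treatment required")
        if any(b <= a for a, b in zip(self.treatments, self.treatments[1:])):
            raise ValueError("treatments must be strictly increasing")
        if len(self.n_mean_by_treatment) != len(self.treatments):
            raise ValueError("n_mean_by_treatment must match treatments")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_sd < 0:
            raise ValueError("n_sd must be >= 0")
        if self.n_plots_per_treatment < 1 or self.n_samples_per_plot < 1:
            raise ValueError("counts must be >= 1")

    @property
    def n_samples(self) -> int:
        return (len(self.treatments) * self.n_plots_per_treatment
                * self.n_samples_per_plot)


# Leaf N content is clipped to the physiological range seen in the field data.
N_CONTENT_LO = 1.0
N_CONTENT_HI = 5.0


def _chlorophyll_saturation(n_content: np.ndarray) -> np.ndarray:
    """Saturating chlorophyll response to leaf N (Michaelis-Menten, K=2 mg/g).

    Chlorophyll accumulation saturates at high N supply; this is what makes
    the reflectance-N link mildly nonlinear and favours nonlinear inverse
    models, as observed on real leaves.
    """
    return n_content / (n_content + 2.0)


# Stochastic components of a measured leaf spectrum, expressed as multiples
# of the band-noise sd so that noise_sd=0 yields spectra that are exact
# functions of leaf N:
#   - chlorophyll-N decoupling: effective chlorophyll-driving N is
#     N*(1+eps), eps ~ N(0, CHL_CV_FACTOR*noise_sd); at the default
#     noise_sd=0.01 this is a 15 % CV, the loose chlorophyll-nitrogen
#     coupling typical of field leaves,
#   - multiplicative scatter: the whole curve is scaled by
#     1 + N(0, SCATTER_FACTOR*noise_sd) (5 % at default), the leaf-clip
#     repositioning/scatter variability that motivates MSC/SNV correction,
#   - NIR plateau offset: N(0, PLATEAU_FACTOR*noise_sd) (2 % at default),
#     leaf structural variability.
CHL_CV_FACTOR = 15.0
SCATTER_FACTOR = 5.0
PLATEAU_FACTOR = 2.0


def leaf_reflectance(n_content: np.ndarray,
                     structure: np.ndarray | None = None) -> np.ndarray:
    """Noise-free leaf reflectance curves for given N contents.

    The curve blends a visible region (green peak at 555 nm whose height
    drops as chlorophyll rises) into a NIR plateau through a sigmoid red
    edge near 710-720 nm that shifts to longer wavelengths with N.
    ``structure`` is an optional per-sample NIR plateau offset emulating
    leaf structural variability.
    """
    n_content = np.atleast_1d(np.asarray(n_content, dtype=float))
    u = _chlorophyll_saturation(n_content)[:, None]
    lam = wavelengths()[None, :]

    edge_pos = 710.0 + 12.0 * u
    s = expit((lam - edge_pos) / 18.0)

    green = 0.30 * (1.0 - 0.75 * u) * np.exp(-((lam - 555.0) / 35.0) ** 2)
    visible = 0.07 + green

    plateau = 0.50
    if structure is not None:
        plateau = plateau + np.asarray(structure, dtype=float)[:, None]
    nir = plateau - 0.04 * (lam - 750.0) / 250.0 * s

    return visible * (1.0 - s) + nir * s


def generate_samples(config: SimulationConfig) -> pd.DataFrame:
    """Generate a sample table: one row per leaf.

    Columns: ``sample_id``, ``plot_id``, ``treatment`` (kg/ha),
    ``n_content`` (mg/g) and reflectance columns ``R401``..``R1000``.
    Deterministic for a fixed seed.  Per-sample leaf N is drawn from the
    treatment's normal distribution and clipped to [1, 5] mg/g; the
    spectrum is the deterministic leaf curve of a chlorophyll driver
    loosely coupled to N, distorted by multiplicative scatter, a NIR
    plateau offset and i.i.d. Gaussian band noise (all stochastic spectrum
    components scale with ``noise_sd``; see the module constants).  With
    ``noise_sd=0`` the reflectance is an exact function of leaf N.
    """
    rng = np.random.default_rng(config.seed)
    rows_meta: list[tuple[str, str, int, float]] = []
    n_values: list[float] = []
    for t, mu in zip(config.treatments, config.n_mean_by_treatment):
        for p in range(1, config.n_plots_per_treatment + 1):
            plot_id = f"N{t}-P{p}"
            for s in range(config.n_samples_per_plot):
                n = float(np.clip(rng.normal(mu, config.n_sd),
                                  N_CONTENT_LO, N_CONTENT_HI))
                sample_id = f"{plot_id}-S{s + 1:02d}"
                rows_meta.append((sample_id, plot_id, t, n))
                n_values.append(n)

    n_arr = np.array(n_values)
    m = n_arr.size
    chl_eps = rng.normal(0.0, CHL_CV_FACTOR * config.noise_sd, size=m)
    chl_eps = np.clip(chl_eps, -0.45, 0.45)
    n_eff = np.clip(n_arr * (1.0 + chl_eps), 0.5, 6.0)
    structure = rng.normal(0.0, PLATEAU_FACTOR * config.noise_sd, size=m)
    scatter = 1.0 + rng.normal(0.0, SCATTER_FACTOR * config.noise_sd, size=m)
    refl = leaf_reflectance(n_eff, structure) * scatter[:, None]
    refl = refl + rng.normal(0.0, config.noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.0, 1.0)

    meta = pd.DataFrame(rows_meta,
                        columns=["sample_id", "plot_id", "treatment",
                                 "n_content"])
    spectra = pd.DataFrame(refl, columns=REFLECTANCE_COLUMNS)
    return pd.concat([meta, spectra], axis=1)


# Yield response: quadratic in applied N with its vertex at 95 kg/ha,
# calibrated to the observed extremes (261.99 kg/667 m^2 without N,
# ~387 kg/667 m^2 at the optimum) so that over the 0/50/100/150 grid the
# 100 kg/ha treatment yields most and over-fertilization at 150 kg/ha
# yields less than 50 kg/ha, matching the field ordering.
_YIELD_MAX = 387.15
_YIELD_VERTEX = 95.0
_YIELD_CURV = (_YIELD_MAX - 261.99) / _YIELD_VERTEX**2


def generate_yields(config: SimulationConfig) -> pd.DataFrame:
    """Per-treatment grain yield table (kg per 667 m^2), deterministic."""
    t = np.asarray(config.treatments, dtype=float)
    y = _YIELD_MAX - _YIELD_CURV * (t - _YIELD_VERTEX) ** 2
    if np.any(y <= 0):
        raise ValueError("yield model produced non-positive yields for the "
                         "configured treatments")
    return pd.DataFrame({"treatment": list(config.treatments), "yield": y})


def reflectance_matrix(samples: pd.DataFrame) -> np.ndarray:
    """Reflectance block of a sample table as a (samples, 600) float array."""
    return samples[REFLECTANCE_COLUMNS].to_numpy(dtype=float)


def make_nonlinear_problem(n_samples: int = 259,
                           n_features: int = 10,
                           noise_sd: float = 0.2,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Reference nonlinear regression benchmark for the inverse models.

    Emulates the structure of reduced difference-spectrum features: a
    single latent driver (the nitrogen status) loads on every feature, the
    first three ("bands") most strongly, with independent per-feature
    noise; the response is a smooth exponential function of the mean of
    those three bands plus Gaussian noise (default sd 0.2 mg/g, the scale
    of the leaf N-difference residuals).  An exponential feature-response
    link leaves a linear model a substantial but incomplete share of the
    signal, so the benchmark discriminates nonlinear from linear
    regressors the way the real inverse problem does.
    """
    if n_features < 3:
        raise ValueError("need at least 3 features")
    rng = np.random.default_rng(seed)
    t = rng.normal(size=n_samples)
    loadings = np.full(n_features, 0.5)
    loadings[:3] = (1.0, 0.9, 0.8)
    feat_noise = np.full(n_features, 0.5)
    feat_noise[:3] = 0.3
    X = t[:, None] * loadings + rng.normal(size=(n_samples, n_features)) * feat_noise
    s = X[:, :3].mean(axis=1)
    y = np.exp(0.9 * s) + rng.normal(0.0, noise_sd, size=n_samples)
    return X, y


def make_planted_problem(n_samples: int,
                         n_bands: int,
                         planted: tuple[int, ...],
                         seed: int = 0,
                         signal_sd: float = 1.0,
                         background_sd: float = 0.3,
                         noise_sd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Planted-band benchmark for wavelength-selection power studies.

    Informative bands carry independent unit-variance signal; the remaining
    bands carry lower-variance independent background, emulating a spectrum
    whose information concentrates in a few bands.  The response is a linear
    combination of the planted bands (coefficients 1, 2, 3, ...) plus
    optional noise, so exact recovery of the planted positions is
    well-defined.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, background_sd, size=(n_samples, n_bands))
    X[:, list(planted)] = rng.normal(0.0, signal_sd,
                                     size=(n_samples, len(planted)))
    coefs = np.arange(1, len(planted) + 1, dtype=float)
    y = X[:, list(planted)] @ coefs
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_samples)
    return X, y
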