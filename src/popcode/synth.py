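"""Synthetic populations: heterogeneous von Mises tuning and 3-neuron fixtures.

The heterogeneous ensemble models direction-tuned neurons whose firing rate
follows a von Mises bump ``alpha * exp(kappa * (cos(theta - phi) - 1))`` with
random amplitude (chi-square, 3 df, scaled to mean 19 spikes/s) and random
log-width, preferred directions equally spaced on the circle, and Poisson
count variability in a fixed counting window.  The encoded stimulus is the
2-D unit vector ``(cos theta, sin theta)`` with theta uniform.

Moments (cross-covariance L, mean-response covariance, stimulus covariance)
are computed by deterministic trapezoid quadrature on a uniform circular grid
— spectrally accurate for these smooth periodic integrands.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .measures import PopulationStats

__all__ = [
    "TuningEnsemble",
    "Fixture",
    "sample_population",
    "tuning_curves",
    "population_moments",
    "fixture",
    "fixture_names",
]

DEFAULT_WINDOW_MS = 100.0
AMPLITUDE_MEAN = 19.0  # spikes/s, chi-square with 3 df scaled to this mean
LOG_WIDTH_MEAN = 2.0  # mean of the underlying normal for log-widths
LOG_WIDTH_SD = 2.0  # SD of the underlying normal for log-widths


@dataclass(frozen=True)
class TuningEnsemble:
    """Per-neuron von Mises tuning parameters and the counting window (ms)."""

    alphas: np.ndarray
    kappas: np.ndarray
    phis: np.ndarray
    window: float = DEFAULT_WINDOW_MS

    def __post_init__(self):
        a = np.asarray(self.alphas, dtype=float)
        k = np.asarray(self.kappas, dtype=float)
        p = np.asarray(self.phis, dtype=float)
        if not (a.shape == k.shape == p.shape):
            raise ValueError("alphas, kappas, phis must have identical shapes")
        if np.any(a <= 0) or np.any(k <= 0):
            raise ValueError("alphas and kappas must be positive")
        if p.size > 1 and np.any(np.diff(p) <= 0):
            raise ValueError("phis must be strictly increasing")
        if self.window <= 0:
            raise ValueError("window must be positive")
        object.__setattr__(self, "alphas", a)
        object.__setattr__(self, "kappas", k)
        object.__setattr__(self, "phis", p)

    @property
    def n_neurons(self) -> int:
        return self.alphas.size


def sample_population(
    n_neurons: int, rng: np.random.Generator, window: float = DEFAULT_WINDOW_MS
) -> TuningEnsemble:
    """Random heterogeneous ensemble (deterministic under a fixed generator)."""
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    alphas = rng.chisquare(3, size=n_neurons) * (AMPLITUDE_MEAN / 3.0)
    kappas = np.exp(rng.normal(LOG_WIDTH_MEAN, LOG_WIDTH_SD, size=n_neurons))
    phis = np.arange(n_neurons) * (2.0 * np.pi / n_neurons)
    return TuningEnsemble(alphas=alphas, kappas=kappas, phis=phis, window=window)


def tuning_curves(ens: TuningEnsemble, thetas: np.ndarray) -> np.ndarray:
    """Firing rates (spikes/s), shape (N, len(thetas))."""
    thetas = np.asarray(thetas, dtype=float)
    d = thetas[None, :] - ens.phis[:, None]
    return ens.alphas[:, None] * np.exp(ens.kappas[:, None] * (np.cos(d) - 1.0))


def population_moments(
    ens: TuningEnsemble, grid_size: int = 512, component: int | None = None
) -> PopulationStats:
    """Sufficient statistics of the ensemble on a uniform stimulus grid.

    Stimulus: unit vector (cos theta, sin theta), theta ~ Uniform[0, 2pi), so
    the stimulus covariance is I/2.  Spike counts are Poisson in the counting
    window, hence each neuron's (stimulus-averaged) noise variance equals its
    mean count.

    ``component=0`` (or 1) restricts decoding to the single stimulus
    coordinate cos(theta) (or sin(theta)), producing a scalar-stimulus
    problem — where the polygon feasibility test applies.
    """
    if grid_size < 64:
        raise ValueError("grid_size must be at least 64")
    thetas = np.arange(grid_size) * (2.0 * np.pi / grid_size)
    window_s = ens.window / 1000.0
    counts = tuning_curves(ens, thetas) * window_s  # (N, G) mean spike counts
    if np.allclose(counts, 0.0):
        raise ValueError("degenerate ensemble: all-zero tuning")
    s = np.stack([np.cos(thetas), np.sin(thetas)])  # (2, G)

    if component is not None:
        if component not in (0, 1):
            raise ValueError("component must be 0, 1 or None")
        s = s[component : component + 1]
    mean_counts = counts.mean(axis=1)
    cross_cov = counts @ s.T / grid_size  # E[mu s^T], E[s] = 0
    mean_resp_cov = counts @ counts.T / grid_size - np.outer(mean_counts, mean_counts)
    mean_resp_cov = 0.5 * (mean_resp_cov + mean_resp_cov.T)
    stim_cov = 0.5 * np.eye(s.shape[0])
    sensitivities = cross_cov @ np.linalg.inv(stim_cov)  # regression slope of mu on s
    return PopulationStats(
        sensitivities=sensitivities,
        cross_cov=cross_cov,
        mean_resp_cov=mean_resp_cov,
        noise_vars=np.maximum(mean_counts, 1e-12),
        stim_cov=stim_cov,
    )


# ---------------------------------------------------------------------------
# 3-neuron fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    """A named 3-neuron example with its statistics and optional extras."""

    name: str
    stats: PopulationStats
    noise_corr: np.ndarray | None = None  # pairwise correlations, when fixed
    stimulus_means: tuple[np.ndarray, np.ndarray] | None = None
    slice_constraint: str | None = None  # e.g. "rho13 == rho23"


def _fixture_payload() -> dict:
    text = resources.files("popcode.data").joinpath("fixtures.json").read_text()
    manifest = json.loads(
        resources.files("popcode.data").joinpath("manifest.json").read_text()
    )
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != manifest["fixtures.json"]:
        raise RuntimeError("fixture data does not match its checksum manifest")
    return json.loads(text)


def fixture_names() -> list[str]:
    return sorted(_fixture_payload().keys())


def fixture(name: str) -> Fixture:
    """Load a packaged 3-neuron fixture by name.

    Names: ``fig1_caseA`` … ``fig1_caseD`` (two-stimulus discrimination with
    four noise-correlation choices), ``fig2`` (the 2-D correlation slice with
    rho13 = rho23), ``fig3_A`` / ``fig3_B`` (boundary optima; A attains the
    noise-free bound, B does not).
    """
    payload = _fixture_payload()
    if name not in payload:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(payload)}")
    raw = payload[name]
    stats = PopulationStats(
        sensitivities=np.asarray(raw["sensitivities"], dtype=float),
        cross_cov=np.asarray(raw["cross_cov"], dtype=float),
        mean_resp_cov=np.asarray(raw["mean_resp_cov"], dtype=float),
        noise_vars=np.asarray(raw["noise_vars"], dtype=float),
        stim_cov=np.asarray(raw["stim_cov"], dtype=float),
    )
    means = None
    if "stimulus_means" in raw:
        means = (
            np.asarray(raw["stimulus_means"][0], dtype=float),
            np.asarray(raw["stimulus_means"][1], dtype=float),
        )
    corr = np.asarray(raw["noise_corr"], dtype=float) if "noise_corr" in raw else None
    return Fixture(
        name=name,
        stats=stats,
        noise_corr=corr,
        stimulus_means=means,
        slice_constraint=raw.get("slice_constraint"),
    )
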