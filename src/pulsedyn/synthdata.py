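"""Synthetic transient-absorption experiments for testing and benchmarking.

The default benchmark emulates a three-species sequential photoreaction
(lifetimes 1.87 s and 34.8 s feeding a long-lived photoproduct) sampled at 91
logarithmically spaced delays over a 300 s time base, with three overlapping
sums-of-Gaussians spectra over 100 detection channels.  Optional white noise
is added at a stated fraction of the maximum of each basis spectrum and of
each concentration profile before the two factors are multiplied, mimicking
spectral detector noise plus shot-to-shot amplitude jitter.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DataMatrix
from .kinetics import KineticScheme, build_sequential_scheme, solve_concentrations
from .photoselection import MultipulseSchedule, multipulse_weights
from .response import IRFModel, chirp_location, exp_conv_irf

__all__ = ["BenchmarkSpec", "make_benchmark", "make_chirped_irf_dataset",
           "make_multipulse_experiment", "gaussian_band"]


def gaussian_band(channels, centre, width, amplitude):
    """One Gaussian spectral line shape over a channel axis."""
    channels = np.asarray(channels, dtype=float)
    return amplitude * np.exp(-0.5 * ((channels - centre) / width) ** 2)


#: (centre, width, amplitude) Gaussian bands of each default benchmark spectrum;
#: chosen once with strong overlap near pixel 50 so model mismatch shows up as
#: compensating amplitudes there.
DEFAULT_BANDS = (
    ((25.0, 8.0, 1.0), (55.0, 15.0, 0.35)),
    ((50.0, 10.0, 0.9),),
    ((70.0, 9.0, 0.7), (40.0, 20.0, 0.25)),
)


@dataclass
class BenchmarkSpec:
    """Parameters of the sequential-decay benchmark dataset.

    ``lifetimes`` lists the per-species lifetimes in seconds with 0 meaning a
    terminal long-lived species; ``noise_fraction`` scales the white noise (0
    or 0.10 in the reference conditions).
    """

    lifetimes: tuple[float, ...] = (1.87, 34.8, 0.0)
    n_times: int = 91
    t_start: float = 0.1
    t_end: float = 300.0
    n_channels: int = 100
    bands: tuple = DEFAULT_BANDS
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.lifetimes):
            raise ValueError("lifetimes must be >= 0 (0 = long-lived)")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must lie in [0, 1)")
        if len(self.bands) != len(self.lifetimes):
            raise ValueError("need one band set per species")

    @property
    def rates(self) -> list[float]:
        return [0.0 if t == 0 else 1.0 / t for t in self.lifetimes]

    def scheme(self) -> KineticScheme:
        return build_sequential_scheme(self.rates)

    def times(self) -> np.ndarray:
        return np.logspace(np.log10(self.t_start), np.log10(self.t_end), self.n_times)

    def channels(self) -> np.ndarray:
        return np.arange(1.0, self.n_channels + 1.0)

    def spectra(self) -> np.ndarray:
        ch = self.channels()
        return np.array([
            np.sum([gaussian_band(ch, *b) for b in bands], axis=0)
            for bands in self.bands
        ])


def make_benchmark(spec: BenchmarkSpec | None = None) -> DataMatrix:
    """Generate the sequential three-species benchmark matrix.

    data = concentrations(sequential scheme) × spectra.  With
    ``noise_fraction`` > 0, white noise at that fraction of each basis
    spectrum's maximum is added to the spectra and, at the fraction of each
    profile's maximum, to the concentration profiles, before multiplication.
    The noiseless concentrations come from the exact (eigendecomposition)
    solver, so the matrix has numerically exact rank 3.
    """
    spec = spec or BenchmarkSpec()
    times = spec.times()
    conc = solve_concentrations(spec.scheme(), times, 1e-12).values
    spectra = spec.spectra()
    if spec.noise_fraction > 0:
        rng = np.random.default_rng(spec.seed)
        conc = conc + rng.standard_normal(conc.shape) * (
            spec.noise_fraction * np.max(np.abs(conc), axis=0)
        )
        spectra = spectra + rng.standard_normal(spectra.shape) * (
            spec.noise_fraction * np.max(np.abs(spectra), axis=1, keepdims=True)
        )
    values = conc @ spectra
    meta = {
        "generator": "pulsedyn.synthdata.make_benchmark",
        "lifetimes_s": ", ".join(str(t) for t in spec.lifetimes),
        "noise_fraction": str(spec.noise_fraction),
        "seed": str(spec.seed),
    }
    return DataMatrix(times, spec.channels(), values, meta)


def make_chirped_irf_dataset(
    scheme: KineticScheme,
    irf: IRFModel,
    times,
    channels,
    amplitudes: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[DataMatrix, np.ndarray]:
    """Per-channel IRF-convolved kinetics with a wavelength-dependent onset.

    Each species' exponential modes are convolved with the Gaussian IRF whose
    centre follows the chirp polynomial μ(λ).  Returns the data matrix and the
    ground-truth μ(λ) per channel for round-trip tests.
    """
    times = np.asarray(times, dtype=float)
    channels = np.asarray(channels, dtype=float)
    K = scheme.rate_matrix()
    c0 = scheme.initial_vector()
    w, V = np.linalg.eig(K)
    w, V = np.real(w), np.real(V)
    a = np.linalg.solve(V, c0)
    mode_weights = (V * a).T  # (mode, species)
    if amplitudes is None:
        rng_amp = np.random.default_rng(seed + 1)
        amplitudes = 0.5 + rng_amp.random((scheme.n_species, channels.size))
    values = np.empty((times.size, channels.size))
    for j, lam in enumerate(channels):
        basis = np.column_stack(
            [exp_conv_irf(times, max(-r, 0.0), irf, lam) for r in w]
        )
        conc = basis @ mode_weights
        values[:, j] = conc @ amplitudes[:, j]
    if noise > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.standard_normal(values.shape) * noise * np.max(np.abs(values))
    truth = np.asarray(chirp_location(channels, irf), dtype=float)
    data = DataMatrix(times, channels, values,
                      {"generator": "pulsedyn.synthdata.make_chirped_irf_dataset"})
    return data, truth


def make_multipulse_experiment(
    scheme: KineticScheme,
    schedule: MultipulseSchedule,
    times=None,
    channels=None,
    seed: int = 0,
) -> tuple[DataMatrix, DataMatrix, DataMatrix, DataMatrix]:
    """Three consistent synthetic experiments plus the planted intermediate.

    The pump-probe (S_pp) and dump-probe (S_dp) matrices carry kinetics of the
    supplied scheme with random smooth spectra; the intermediate signal decays
    with the scheme's slowest finite rate.  S_pdp is assembled as
    S_pp + w_gs·S_dp + w_int·I with the weights of
    :func:`pulsedyn.photoselection.multipulse_weights`, so
    :func:`pulsedyn.photoselection.pure_intermediate_signal` inverts the
    construction exactly.  Returns (S_pp, S_dp, S_pdp, intermediate_truth).
    """
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.linspace(0.0, 50.0, 120)
    if channels is None:
        channels = np.arange(1.0, 41.0)
    times = np.asarray(times, dtype=float)
    channels = np.asarray(channels, dtype=float)
    conc = solve_concentrations(scheme, times, 1e-12).values
    spectra_pp = rng.standard_normal((scheme.n_species, channels.size))
    spectra_dp = rng.standard_normal((scheme.n_species, channels.size))
    finite = [k for k in np.diag(-scheme.rate_matrix()) if k > 0]
    k_int = min(finite) if finite else 0.0
    int_profile = np.exp(-k_int * times)
    int_spectrum = rng.standard_normal(channels.size)
    intermediate = np.outer(int_profile, int_spectrum)

    weights = multipulse_weights(schedule)
    v_pp = conc @ spectra_pp
    v_dp = conc @ spectra_dp
    v_pdp = v_pp + weights["ground_state"] * v_dp + weights["intermediate"] * intermediate
    mk = lambda v, tag: DataMatrix(  # noqa: E731
        times.copy(), channels.copy(), v,
        {"generator": "pulsedyn.synthdata.make_multipulse_experiment", "experiment": tag},
    )
    return (mk(v_pp, "pump-probe"), mk(v_dp, "dump-probe"), mk(v_pdp, "pump-dump-probe"),
            mk(intermediate, "intermediate-truth"))
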