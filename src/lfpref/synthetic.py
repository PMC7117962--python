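"""Synthetic epoched multielectrode LFP with a shared spectral component.

Spectral coefficients are drawn directly in the frequency domain: for
every trial and positive FFT bin ``f`` each electrode receives

    V_e(f) = sqrt(c(f) P(f)) G(f) + sqrt((1 - c(f)) P(f)) N_e(f)

with ``G`` shared across electrodes and ``N_e`` independent, both unit
variance circularly-symmetric complex Gaussian.  Total expected power is
``P(f) = scale * f**-alpha + floor + bumps`` and the shared source
carries the fraction ``c(f)``, which sets the inter-electrode
cross-spectral coherency exactly.  Drawing in the frequency domain makes
single-taper powers exponential and amplitudes Rayleigh across trials by
construction, which is the structure the downstream phase-flip analyses
rely on.

Time series are obtained by inverse real FFT (conjugate-symmetric
spectrum, DC and Nyquist zeroed), so the raw periodogram of a generated
epoch recovers ``P(f)`` in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import hyp2f1

from lfpref.geometry import DEFAULT_PITCH, ElectrodeGrid, build_grid
from lfpref.referencing import EpochedRecording


def logistic_common_fraction(
    low_value: float = 0.6, midpoint_hz: float = 80.0, width_hz: float = 20.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Default shared-power fraction: logistic decay from ``low_value``
    toward zero with the given midpoint and width."""

    def c_of_f(f: np.ndarray) -> np.ndarray:
        return low_value / (1.0 + np.exp((np.asarray(f, float) - midpoint_hz) / width_hz))

    return c_of_f


@dataclass(frozen=True)
class Bump:
    """Gaussian power bump: ``amplitude * exp(-(f-center)^2 / (2 bw^2))``."""

    center_hz: float
    bandwidth_hz: float
    amplitude: float


@dataclass(frozen=True)
class LineComponent:
    """Deterministic-amplitude narrowband contaminant (line noise,
    monitor refresh), identical across electrodes, random phase per
    trial."""

    frequency_hz: float
    amplitude: float


@dataclass
class SyntheticConfig:
    n_rows: int = 10
    n_cols: int = 10
    pitch: float = DEFAULT_PITCH
    good_mask: np.ndarray | None = None
    n_trials: int = 200
    epoch_duration: float = 0.5
    sampling_rate: float = 2000.0
    background_exponent: float = 1.5
    background_scale: float = 1000.0
    noise_floor: float = 0.1
    common_fraction: Callable[[np.ndarray], np.ndarray] | None = None
    alpha_bump: Bump | None = None
    gamma_bump: Bump | None = None
    gamma_center_vs_condition: dict[str, float] | None = None
    condition: str | None = None
    line_components: Sequence[LineComponent] = field(default_factory=tuple)
    reference_pickup: float = 0.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        n = self.epoch_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_duration * sampling_rate must be an integer")
        return int(round(n))

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    def grid(self) -> ElectrodeGrid:
        return build_grid(self.n_rows, self.n_cols, self.pitch, self.good_mask)

    def validate(self) -> None:
        _ = self.n_samples
        for bump in (self.alpha_bump, self.gamma_bump):
            if bump is not None and bump.center_hz > self.nyquist:
                raise ValueError(
                    f"bump at {bump.center_hz} Hz exceeds Nyquist {self.nyquist} Hz"
                )
        for line in self.line_components:
            if line.frequency_hz > self.nyquist:
                raise ValueError(
                    f"line component at {line.frequency_hz} Hz exceeds Nyquist"
                )
        c_fn = self.common_fraction or logistic_common_fraction()
        c = np.asarray(c_fn(self.frequencies()), dtype=float)
        if np.any(c < -1e-12) or np.any(c > 1 + 1e-12):
            raise ValueError("common fraction c(f) must lie in [0, 1]")

    def frequencies(self) -> np.ndarray:
        return np.fft.rfftfreq(self.n_samples, d=1.0 / self.sampling_rate)

    def common_fraction_profile(self, f: np.ndarray) -> np.ndarray:
        c_fn = self.common_fraction or logistic_common_fraction()
        return np.clip(np.asarray(c_fn(np.asarray(f, float)), float), 0.0, 1.0)

    def _effective_gamma_bump(self) -> Bump | None:
        bump = self.gamma_bump
        if (
            bump is not None
            and self.gamma_center_vs_condition
            and self.condition in self.gamma_center_vs_condition
        ):
            bump = Bump(
                center_hz=self.gamma_center_vs_condition[self.condition],
                bandwidth_hz=bump.bandwidth_hz,
                amplitude=bump.amplitude,
            )
        return bump

    def power_profile(self, f: np.ndarray) -> np.ndarray:
        """Expected total power P(f) at positive frequencies."""
        f = np.asarray(f, dtype=float)
        with np.errstate(divide="ignore"):
            p = self.background_scale * np.power(
                f, -self.background_exponent, where=f > 0, out=np.zeros_like(f)
            )
        p = p + self.noise_floor
        for bump in (self.alpha_bump, self._effective_gamma_bump()):
            if bump is not None:
                p = p + bump.amplitude * np.exp(
                    -0.5 * ((f - bump.center_hz) / bump.bandwidth_hz) ** 2
                )
        p[f <= 0] = 0.0
        return p


def _complex_normal(rng: np.random.Generator, shape) -> np.ndarray:
    """Unit-variance circularly-symmetric complex Gaussian draws."""
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)


def generate_recording(
    config: SyntheticConfig,
) -> tuple[EpochedRecording, dict]:
    """Generate an epoched recording plus its ground-truth record.

    One RNG stream per recording; per-trial sub-streams are spawned
    deterministically from the seed, so identical configs produce
    bit-identical output.
    """
    config.validate()
    grid = config.grid()
    n = config.n_samples
    freqs = config.frequencies()
    n_bins = len(freqs)
    p = config.power_profile(freqs)
    c = config.common_fraction_profile(freqs)
    c[p <= 0] = 0.0

    shared_amp = np.sqrt(c * p)
    indep_amp = np.sqrt((1.0 - c) * p)
    pickup_amp = config.reference_pickup * np.sqrt(p)

    # rfft convention: E|X(f)|^2 = P(f) makes the boxcar periodogram
    # |rfft(x)|^2 an unbiased estimate of P(f).
    line_bins = []
    for line in config.line_components:
        b = int(round(line.frequency_hz * n / config.sampling_rate))
        line_bins.append((b, line.amplitude * n / 2.0))

    n_elec = grid.n_electrodes
    samples = np.empty((n_elec, config.n_trials, n), dtype=float)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    for t, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        g = _complex_normal(rng, n_bins)
        noise = _complex_normal(rng, (n_elec, n_bins))
        pickup = _complex_normal(rng, n_bins)
        spectrum = (
            shared_amp * g[None, :]
            + indep_amp * noise
            + pickup_amp * pickup[None, :]
        )
        for b, coeff_amp in line_bins:
            phase = rng.uniform(-np.pi, np.pi)
            spectrum[:, b] += coeff_amp * np.exp(1j * phase)
        spectrum[:, 0] = 0.0
        if n % 2 == 0:
            spectrum[:, -1] = 0.0
        samples[:, t, :] = np.fft.irfft(spectrum, n=n, axis=-1)

    rec = EpochedRecording(
        samples=samples,
        sampling_rate=config.sampling_rate,
        grid=grid,
        scheme="single-wire",
        lineage=("synthetic",),
    )
    ground_truth = {
        "frequencies_hz": freqs,
        "power": p,
        "common_fraction": c,
        "reference_pickup": config.reference_pickup,
        "seed": config.seed,
    }
    return rec, ground_truth


def expected_coherence(config: SyntheticConfig, f: float) -> float:
    """Model cross-spectral coherency between two electrodes at ``f``.

    For the equal-power shared-component model the coherency equals the
    shared power fraction c(f) exactly (the reference-pickup term adds
    a fully shared contribution on top).
    """
    if f > config.nyquist:
        raise ValueError(f"frequency {f} Hz exceeds Nyquist {config.nyquist} Hz")
    c = float(config.common_fraction_profile(np.asarray([f]))[0])
    rho2 = config.reference_pickup**2
    # shared power: (c + rho^2) P; total power: (1 + rho^2) P
    return (c + rho2) / (1.0 + rho2)


def expected_phase_coherence(config: SyntheticConfig, f: float) -> float:
    """Large-trial expectation of the phase-locking statistic at ``f``.

    The phase-locking value of a bivariate circular Gaussian with
    coherency rho converges to (pi/4) rho 2F1(1/2, 1/2; 2; rho^2),
    which is below rho except at 0 and 1.
    """
    rho = expected_coherence(config, f)
    return plv_of_coherency(rho)


def plv_of_coherency(rho: float) -> float:
    """Asymptotic phase-locking value of a circular Gaussian pair with
    cross-spectral coherency ``rho``."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("coherency must lie in [0, 1]")
    if rho == 1.0:
        return 1.0
    return float((np.pi / 4.0) * rho * hyp2f1(0.5, 0.5, 2.0, rho**2))


def coherence_bias_floor(n_trials: int) -> float:
    """Expected phase-locking value of fully independent phases.

    The resultant of N uniform unit phasors has expectation
    sqrt(pi) / (2 sqrt(N)).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(n_trials)))
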