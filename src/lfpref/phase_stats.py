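"""Circular statistics, pairwise phase profiles and the
average-reference phase-flip analyses.

Phase differences are oriented as ``phi_a - phi_b`` with (a, b) the
stored pair order; the mean of absolute differences is available where
orientation ambiguity matters.  All angles are wrapped to (-pi, pi].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lfpref.geometry import PairTable
from lfpref.spectral import SpectralCoefficients

logger = logging.getLogger(__name__)

#: Below this resultant length the circular mean direction is undefined.
UNDEFINED_MEAN_R = 1e-6


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.mod(-theta + np.pi, 2 * np.pi)
    return np.pi - wrapped


@dataclass(frozen=True)
class CircularMean:
    """Mean direction and resultant length of a set of angles.

    ``angle`` is NaN (and ``defined`` False) when the resultant is too
    short to determine a direction, e.g. for antipodal angle sets.
    """

    angle: float
    R: float

    @property
    def defined(self) -> bool:
        return self.R >= UNDEFINED_MEAN_R and np.isfinite(self.angle)


def circular_mean(angles: np.ndarray) -> CircularMean:
    """Argument and modulus of the mean unit phasor."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    resultant = np.exp(1j * angles).mean()
    r = float(np.abs(resultant))
    if r < UNDEFINED_MEAN_R:
        return CircularMean(angle=np.nan, R=r)
    return CircularMean(angle=float(wrap_angle(np.angle(resultant))), R=r)


def angular_deviation(R: float | np.ndarray) -> float | np.ndarray:
    """Circular spread sqrt(2 (1 - R)), bounded on [0, sqrt(2)]."""
    R = np.asarray(R, dtype=float)
    if np.any(R < -1e-12) or np.any(R > 1 + 1e-12):
        raise ValueError("mean resultant length must lie in [0, 1]")
    out = np.sqrt(2.0 * np.clip(1.0 - R, 0.0, 1.0))
    return float(out) if out.ndim == 0 else out


def _check_nonzero(coeffs: np.ndarray, label: str) -> None:
    zero = np.abs(coeffs) == 0
    if zero.any():
        trial = int(np.argwhere(zero)[0][0])
        raise ValueError(
            f"zero-amplitude coefficient in {label} at trial {trial}: phase undefined"
        )


def phase_differences(coeffs_a: np.ndarray, coeffs_b: np.ndarray) -> np.ndarray:
    """Per-trial phase differences arg(a) - arg(b), wrapped."""
    coeffs_a = np.asarray(coeffs_a)
    coeffs_b = np.asarray(coeffs_b)
    if coeffs_a.shape != coeffs_b.shape:
        raise ValueError("coefficient arrays must have matching shapes")
    _check_nonzero(coeffs_a, "first signal")
    _check_nonzero(coeffs_b, "second signal")
    return wrap_angle(np.angle(coeffs_a * np.conj(coeffs_b)))


def phase_coherence(coeffs_a: np.ndarray, coeffs_b: np.ndarray) -> float | np.ndarray:
    """Phase-locking value: modulus of the trial-mean unit phasor of
    phase differences.

    Input arrays are (n_trials,) or (n_trials, n_freq); the trial axis
    is the first one.  Fully out-of-phase signals (constant pi
    difference) are perfectly coherent: the statistic ignores the mean
    offset.
    """
    deltas = phase_differences(coeffs_a, coeffs_b)
    if deltas.shape[0] < 2:
        raise ValueError("phase coherence needs at least 2 trials")
    out = np.abs(np.exp(1j * deltas).mean(axis=0))
    return float(out) if out.ndim == 0 else out


def pairwise_phase_consistency(deltas: np.ndarray) -> float | np.ndarray:
    """Unbiased phase-consistency: mean over unordered trial pairs of
    cos(delta_j - delta_k).

    Computed via the identity PPC = (N C^2 - 1) / (N - 1) with C the
    phase-locking value; expectation 0 for uniform phases at any N.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.shape[0]
    if n < 2:
        raise ValueError("PPC needs at least 2 trials")
    c = np.abs(np.exp(1j * deltas).mean(axis=0))
    out = (n * c**2 - 1.0) / (n - 1.0)
    return float(out) if out.ndim == 0 else out


def amplitude_of_sum(
    A1: np.ndarray, theta1: np.ndarray, A2: np.ndarray, theta2: np.ndarray
) -> np.ndarray:
    """Amplitude of the sum of two equal-frequency sinusoids:
    sqrt(A1^2 + A2^2 + 2 A1 A2 cos(theta1 - theta2))."""
    A1, A2 = np.asarray(A1, float), np.asarray(A2, float)
    if np.any(A1 < 0) or np.any(A2 < 0):
        raise ValueError("amplitudes must be non-negative")
    arg = A1**2 + A2**2 + 2 * A1 * A2 * np.cos(np.asarray(theta1) - np.asarray(theta2))
    return np.sqrt(np.clip(arg, 0.0, None))


# ---------------------------------------------------------------------------
# pairwise profiles


def pair_phase_stats(
    coeffs: SpectralCoefficients, pairs: PairTable
) -> pd.DataFrame:
    """Per-pair, per-frequency circular statistics of phase differences.

    Columns: pair ids, distance, bin, shared flags, frequency, C_phase
    (= resultant length of per-trial phase differences), circular mean
    phase difference, angular deviation, trial count.
    """
    raw = coeffs.single_taper()  # (elec, trial, freq)
    _check_nonzero(raw, "spectral coefficients")
    unit = raw / np.abs(raw)
    n_trials = unit.shape[1]
    idx_a = coeffs_index(coeffs, pairs.id_a)
    idx_b = coeffs_index(coeffs, pairs.id_b)

    # resultants for all electrode pairs at once, one frequency at a time
    records = []
    for fi, f in enumerate(coeffs.frequencies):
        u = unit[:, :, fi]
        gram = (u @ u.conj().T) / n_trials
        z = gram[idx_a, idx_b]
        r = np.abs(z)
        mean_phase = np.where(r >= UNDEFINED_MEAN_R, wrap_angle(np.angle(z)), np.nan)
        records.append(
            pd.DataFrame(
                {
                    "id_a": pairs.id_a,
                    "id_b": pairs.id_b,
                    "distance_mm": pairs.distance,
                    "bin": pairs.bin_label,
                    "shared_component": pairs.shared_component,
                    "shared_kind": pairs.shared_kind,
                    "frequency_hz": f,
                    "C_phase": r,
                    "mean_phase_diff": mean_phase,
                    "sigma_phase": angular_deviation(r),
                    "n_trials": n_trials,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def coeffs_index(coeffs: SpectralCoefficients, ids: np.ndarray) -> np.ndarray:
    lookup = {int(e): i for i, e in enumerate(coeffs.electrode_ids)}
    return np.asarray([lookup[int(i)] for i in ids])


def pair_profiles(
    coeffs: SpectralCoefficients, pairs: PairTable
) -> pd.DataFrame:
    """Aggregate pair statistics by distance bin x frequency.

    Shared-component pairs are aggregated separately, never pooled with
    clean pairs.  The bin-level phase difference is the circular mean of
    pair-level mean phase differences; coherence and angular deviation
    are plain means over pairs.  Empty bins are omitted (logged).
    """
    stats = pair_phase_stats(coeffs, pairs)
    stats = stats[stats["bin"] != ""]
    if stats.empty:
        logger.warning("no pairs fall inside the configured distance bins")
        return pd.DataFrame(
            columns=[
                "bin",
                "shared_component",
                "frequency_hz",
                "mean_phase_diff",
                "mean_C_phase",
                "mean_sigma_phase",
                "n_pairs",
            ]
        )

    def agg(group: pd.DataFrame) -> pd.Series:
        angles = group["mean_phase_diff"].to_numpy()
        angles = angles[np.isfinite(angles)]
        if len(angles) > 0:
            cm = circular_mean(angles)
            mean_diff = cm.angle
        else:
            mean_diff = np.nan
        return pd.Series(
            {
                "mean_phase_diff": mean_diff,
                "mean_C_phase": group["C_phase"].mean(),
                "mean_sigma_phase": group["sigma_phase"].mean(),
                "n_pairs": len(group),
            }
        )

    grouped = (
        stats.groupby(["bin", "shared_component", "frequency_hz"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    present = set(grouped["bin"].unique())
    for lo, hi in zip(pairs.bin_edges[:-1], pairs.bin_edges[1:]):
        label = f"({lo:g}, {hi:g}]"
        if label not in present:
            logger.info("distance bin %s is empty and was omitted", label)
    grouped["n_pairs"] = grouped["n_pairs"].astype(int)
    return grouped


# ---------------------------------------------------------------------------
# average-reference flip mechanism

CATEGORIES = ("both", "exactly-one", "neither")


@dataclass
class FlipAnalysis:
    """Trial-level record of the average-reference phase flip.

    Each sample is one (trial, frequency-bin) draw within the analysis
    band; bins are pooled as independent samples.  ``category`` encodes
    whether both, exactly one, or neither of the two signal amplitudes
    exceeded the average-reference amplitude (ties count as not-above).
    """

    amplitude_a: np.ndarray
    amplitude_b: np.ndarray
    amplitude_ref: np.ndarray
    category: np.ndarray
    phase_diff_before: np.ndarray
    phase_diff_after: np.ndarray
    phase_diff_change: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.category)

    def category_fractions(self) -> dict[str, float]:
        n = self.n_samples
        return {c: float((self.category == c).sum()) / n for c in CATEGORIES}

    def mean_abs_change_by_category(self) -> dict[str, float]:
        """Circular mean of |change in phase difference| per category."""
        out = {}
        for c in CATEGORIES:
            sel = self.category == c
            if sel.sum() == 0:
                out[c] = np.nan
                continue
            cm = circular_mean(np.abs(self.phase_diff_change[sel]))
            out[c] = cm.angle
        return out

    def summary(self) -> dict:
        before = circular_mean(self.phase_diff_before)
        after = circular_mean(self.phase_diff_after)
        return {
            "n_samples": self.n_samples,
            "category_fractions": self.category_fractions(),
            "mean_abs_change_by_category": self.mean_abs_change_by_category(),
            "mean_phase_diff_before": before.angle,
            "mean_phase_diff_after": after.angle,
            "R_before": before.R,
            "R_after": after.R,
        }


def flip_analysis(
    coeffs_a: np.ndarray,
    coeffs_b: np.ndarray,
    ref_coeffs: np.ndarray,
) -> FlipAnalysis:
    """Categorize trials by amplitude relative to the average reference
    and record the phase-difference change that referencing induces.

    All three inputs are aligned complex arrays, (n_trials,) or
    (n_trials, n_bins); bins are flattened into the sample axis.
    ``after`` phases come from subtracting the reference coefficient,
    the frequency-domain equivalent of average-referencing the traces.
    """
    a = np.asarray(coeffs_a).ravel()
    b = np.asarray(coeffs_b).ravel()
    ref = np.asarray(ref_coeffs).ravel()
    if not (a.shape == b.shape == ref.shape):
        raise ValueError("coefficient arrays are misaligned across trials")
    amp_a, amp_b, amp_ref = np.abs(a), np.abs(b), np.abs(ref)

    above_a = amp_a > amp_ref
    above_b = amp_b > amp_ref
    category = np.where(
        above_a & above_b,
        "both",
        np.where(above_a | above_b, "exactly-one", "neither"),
    ).astype(object)

    before = phase_differences(a, b)
    after = phase_differences(a - ref, b - ref)
    change = wrap_angle(after - before)
    return FlipAnalysis(
        amplitude_a=amp_a,
        amplitude_b=amp_b,
        amplitude_ref=amp_ref,
        category=category,
        phase_diff_before=before,
        phase_diff_after=after,
        phase_diff_change=change,
    )


def fraction_below_reference(
    coeffs: np.ndarray, ref_coeffs: np.ndarray
) -> np.ndarray:
    """Fraction of trials with signal amplitude strictly below the
    reference amplitude, per electrode and frequency.

    ``coeffs`` is (n_elec, n_trials, n_freq); ``ref_coeffs`` is
    (n_trials, n_freq).  Ties count as not-below.
    """
    coeffs = np.asarray(coeffs)
    ref = np.asarray(ref_coeffs)
    if coeffs.shape[1:] != ref.shape:
        raise ValueError("reference coefficients misaligned with signal")
    return (np.abs(coeffs) < np.abs(ref)[None]).mean(axis=1)


def expected_fraction_below(n_electrodes: int) -> float:
    """Closed-form fraction-below for equal-power independent electrodes
    with the reference being their mean (self included).

    For jointly circular Gaussian (signal, reference) with variances
    (s, r) and real covariance c, P(|ref| > |signal|) =
    (1 - (s - r) / sqrt((s + r)^2 - 4 c^2)) / 2; here r = c = s/n.
    Approaches 1/(n+1), the independent-reference value, for large n.
    """
    n = int(n_electrodes)
    if n < 1:
        raise ValueError("need at least one electrode")
    s, r, c = 1.0, 1.0 / n, 1.0 / n
    return 0.5 * (1.0 - (s - r) / np.sqrt((s + r) ** 2 - 4 * c**2))


def phase_shift_surface(
    flip: FlipAnalysis,
    edges_a: np.ndarray,
    edges_b: np.ndarray,
) -> np.ndarray:
    """Mean |phase-difference change| binned over the amplitude plane
    (A1 - A_ref, A2 - A_ref).

    Returns an (n_bins_a, n_bins_b) array; empty bins are NaN.  With
    phase-aligned inputs the first/third quadrants (both above / both
    below the reference) sit near 0 and the mixed quadrants near pi.
    """
    x = flip.amplitude_a - flip.amplitude_ref
    y = flip.amplitude_b - flip.amplitude_ref
    ix = np.digitize(x, edges_a) - 1
    iy = np.digitize(y, edges_b) - 1
    n_a, n_b = len(edges_a) - 1, len(edges_b) - 1
    surface = np.full((n_a, n_b), np.nan)
    absval = np.abs(flip.phase_diff_change)
    for i in range(n_a):
        for j in range(n_b):
            sel = (ix == i) & (iy == j)
            if sel.any():
                cm = circular_mean(absval[sel])
                surface[i, j] = cm.angle
    return surface
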