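"""Reference schemes for epoched multielectrode recordings.

All schemes act sample-wise in the time domain, so they commute with
linear spectral estimation: re-referencing then taking tapered FFTs is
identical to transforming the FFT coefficients directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from lfpref import geometry
from lfpref.geometry import ElectrodeGrid

SCHEMES = ("single-wire", "average", "bipolar", "csd")


@dataclass
class EpochedRecording:
    """Voltage samples indexed (electrode, trial, time).

    ``lineage`` records the chain of transforms that produced the
    recording (provenance only; not used in computation).
    """

    samples: np.ndarray
    sampling_rate: float
    grid: ElectrodeGrid
    scheme: str = "single-wire"
    lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3:
            raise ValueError("samples must be (electrode, trial, time)")
        if self.samples.shape[0] != self.grid.n_electrodes:
            raise ValueError(
                f"samples have {self.samples.shape[0]} electrodes but grid has "
                f"{self.grid.n_electrodes}"
            )
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")
        if self.scheme == "csd" and self.grid.kind != "csd":
            raise ValueError("csd scheme requires a csd grid")
        if self.scheme == "bipolar" and self.grid.kind != "bipolar-virtual":
            raise ValueError("bipolar scheme requires a bipolar-virtual grid")

    @property
    def n_electrodes(self) -> int:
        return self.samples.shape[0]

    @property
    def n_trials(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[2]

    @property
    def epoch_duration(self) -> float:
        return self.n_samples / self.sampling_rate


def single_wire(rec: EpochedRecording) -> EpochedRecording:
    """Identity pass-through, tagged single-wire.

    The raw recording is already referenced against the physical wire;
    any activity picked up by the wire is part of the samples.
    """
    return replace(
        rec,
        samples=rec.samples.copy(),
        scheme="single-wire",
        lineage=rec.lineage + ("single-wire",),
    )


def average_reference(
    rec: EpochedRecording, subset: np.ndarray | None = None
) -> EpochedRecording:
    """Subtract the per-time-sample mean over ``subset`` from every electrode.

    ``subset`` is a set of electrode ids, defaulting to all electrodes
    in the recording.  Electrodes outside the subset are still
    re-referenced against it.
    """
    if rec.scheme != "single-wire":
        raise ValueError("average reference applies to single-wire recordings")
    if subset is None:
        subset_idx = np.arange(rec.n_electrodes)
    else:
        subset = np.atleast_1d(np.asarray(subset))
        if len(subset) == 0:
            raise ValueError("average-reference subset is empty")
        subset_idx = rec.grid.index_of(subset)
        if len(subset_idx) < 2:
            raise ValueError("average-reference subset needs at least 2 electrodes")
    reference = rec.samples[subset_idx].mean(axis=0, keepdims=True)
    return replace(
        rec,
        samples=rec.samples - reference,
        scheme="average",
        lineage=rec.lineage + (f"average[{len(subset_idx)}]",),
    )


def average_reference_signal(
    rec: EpochedRecording, subset: np.ndarray | None = None
) -> np.ndarray:
    """The reference trace itself: per-time mean over subset, (trial, time)."""
    if subset is None:
        subset_idx = np.arange(rec.n_electrodes)
    else:
        subset_idx = rec.grid.index_of(np.atleast_1d(np.asarray(subset)))
    return rec.samples[subset_idx].mean(axis=0)


def bipolar_reference(
    rec: EpochedRecording, virtual: ElectrodeGrid
) -> EpochedRecording:
    """Minuend minus subtrahend trace for every virtual electrode."""
    if rec.scheme != "single-wire":
        raise ValueError("bipolar reference applies to single-wire recordings")
    if virtual.kind != "bipolar-virtual":
        raise ValueError("bipolar reference needs a bipolar-virtual grid")
    idx_min = rec.grid.index_of(virtual.bipolar_pairs[:, 0])
    idx_sub = rec.grid.index_of(virtual.bipolar_pairs[:, 1])
    samples = rec.samples[idx_min] - rec.samples[idx_sub]
    return EpochedRecording(
        samples=samples,
        sampling_rate=rec.sampling_rate,
        grid=virtual,
        scheme="bipolar",
        lineage=rec.lineage + (f"bipolar[{virtual.n_electrodes}]",),
    )


def csd_reference(rec: EpochedRecording) -> EpochedRecording:
    """CSD transform: center voltage minus the mean of its four
    one-pitch neighbors, restricted to eligible electrodes.

    Follows the printed voltage-difference form (no 1/pitch^2 Laplacian
    scaling); output units remain microvolts.
    """
    if rec.scheme != "single-wire":
        raise ValueError("csd reference applies to single-wire recordings")
    grid = geometry.csd_grid(rec.grid)
    samples = np.empty((grid.n_electrodes, rec.n_trials, rec.n_samples))
    for k, eid in enumerate(grid.electrode_ids):
        row, col = rec.grid.lattice_site(eid)
        neighbor_ids = [
            r * rec.grid.n_cols + c
            for r, c in geometry._neighbor_sites(rec.grid, row, col)
        ]
        idx_center = rec.grid.index_of(eid)[0]
        idx_nbrs = rec.grid.index_of(np.asarray(neighbor_ids))
        samples[k] = rec.samples[idx_center] - rec.samples[idx_nbrs].mean(axis=0)
    return EpochedRecording(
        samples=samples,
        sampling_rate=rec.sampling_rate,
        grid=grid,
        scheme="csd",
        lineage=rec.lineage + (f"csd[{grid.n_electrodes}]",),
    )
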