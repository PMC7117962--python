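"""End-to-end orchestration: simulate -> reference -> spectra -> phase.

Recordings are serialized as a flat little-endian float64 binary array
plus a JSON sidecar carrying shape, order, sampling rate, grid spec,
scheme and lineage; results are CSV tables plus a JSON manifest, all
reproducible from the serialized config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

import lfpref
from lfpref import geometry, phase_stats, referencing, spectral
from lfpref.geometry import DEFAULT_BIN_EDGES, ElectrodeGrid, PairTable
from lfpref.referencing import EpochedRecording
from lfpref.spectral import DEFAULT_MASK, TaperSpec
from lfpref.synthetic import SyntheticConfig, generate_recording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# recording serialization


def _grid_to_dict(grid: ElectrodeGrid) -> dict:
    d = {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "pitch": grid.pitch,
        "good_mask": grid.good_mask.astype(int).tolist(),
        "electrode_ids": grid.electrode_ids.tolist(),
        "positions": grid.positions.tolist(),
        "kind": grid.kind,
    }
    if grid.bipolar_pairs is not None:
        d["bipolar_pairs"] = grid.bipolar_pairs.tolist()
    return d


def _grid_from_dict(d: dict) -> ElectrodeGrid:
    pairs = d.get("bipolar_pairs")
    return ElectrodeGrid(
        n_rows=int(d["n_rows"]),
        n_cols=int(d["n_cols"]),
        pitch=float(d["pitch"]),
        good_mask=np.asarray(d["good_mask"], dtype=bool),
        electrode_ids=np.asarray(d["electrode_ids"], dtype=int),
        positions=np.asarray(d["positions"], dtype=float),
        kind=d["kind"],
        bipolar_pairs=None if pairs is None else np.asarray(pairs, dtype=int),
    )


def write_recording(rec: EpochedRecording, path: str | Path) -> None:
    """Write samples as flat float64 binary with a ``.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rec.samples.astype("<f8").tofile(path)
    sidecar = {
        "shape": list(rec.samples.shape),
        "dtype": "<f8",
        "order": "C",
        "axes": ["electrode", "trial", "time"],
        "sampling_rate": rec.sampling_rate,
        "scheme": rec.scheme,
        "lineage": list(rec.lineage),
        "grid": _grid_to_dict(rec.grid),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_recording(path: str | Path) -> EpochedRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    shape = tuple(sidecar["shape"])
    samples = np.fromfile(path, dtype=sidecar["dtype"])
    if samples.size != int(np.prod(shape)):
        raise ValueError(
            f"sample count {samples.size} does not match sidecar shape {shape}"
        )
    return EpochedRecording(
        samples=samples.reshape(shape),
        sampling_rate=float(sidecar["sampling_rate"]),
        grid=_grid_from_dict(sidecar["grid"]),
        scheme=sidecar["scheme"],
        lineage=tuple(sidecar["lineage"]),
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    synthetic: SyntheticConfig | None = None
    recording_path: str | None = None
    schemes: tuple[str, ...] = ("single-wire", "average", "bipolar", "csd")
    window: tuple[float, float] | None = None
    taper: TaperSpec = field(default_factory=TaperSpec)
    mask_hz: tuple[float, ...] = DEFAULT_MASK
    rolloff: bool = False
    slope_centers: tuple[float, ...] = spectral.DEFAULT_SLOPE_CENTERS
    slope_half_width: float = spectral.DEFAULT_HALF_WIDTH
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    max_distance: float = geometry.DEFAULT_MAX_DISTANCE
    # real-electrode separation used to form bipolar virtual electrodes;
    # defaults to one pitch (nearest-neighbor bipolar derivations)
    bipolar_real_max_distance: float = 0.4
    bands: tuple[tuple[float, float], ...] = ((5.0, 25.0), (200.0, 300.0))
    flip_pair_distance: float | None = None
    out_dir: str = "results"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            syn = d["synthetic"]
            if syn.get("good_mask") is not None:
                syn["good_mask"] = np.asarray(syn["good_mask"]).astype(int).tolist()
            syn["common_fraction"] = (
                None if self.synthetic.common_fraction is None else "custom"
            )
        return d

    def config_hash(self) -> str:
        """Hash of the analysis definition (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_input(config: RunConfig) -> EpochedRecording:
    if (config.synthetic is None) == (config.recording_path is None):
        raise ValueError("provide exactly one of synthetic config or recording path")
    if config.recording_path is not None:
        return read_recording(config.recording_path)
    syn = replace(config.synthetic, seed=config.seed)
    rec, _ = generate_recording(syn)
    return rec


def apply_scheme(rec: EpochedRecording, scheme: str, config: RunConfig):
    """Re-reference and build the matching pair table for one scheme."""
    if scheme == "single-wire":
        out = referencing.single_wire(rec)
        pairs = geometry.unique_pairs(out.grid, config.max_distance, config.bin_edges)
    elif scheme == "average":
        out = referencing.average_reference(rec)
        pairs = geometry.unique_pairs(out.grid, config.max_distance, config.bin_edges)
    elif scheme == "bipolar":
        virtual, _ = geometry.bipolar_virtual_grid(
            rec.grid,
            max_distance=config.bipolar_real_max_distance,
            bin_edges=config.bin_edges,
            include_pairs=False,
        )
        out = referencing.bipolar_reference(rec, virtual)
        pairs = geometry.unique_pairs(virtual, config.max_distance, config.bin_edges)
        pairs = geometry.flag_shared_components(pairs, "bipolar")
    elif scheme == "csd":
        out = referencing.csd_reference(rec)
        pairs = geometry.unique_pairs(out.grid, config.max_distance, config.bin_edges)
        pairs = geometry.flag_shared_components(pairs, "csd")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return out, pairs


def _flip_pair(pairs: PairTable, target_mm: float) -> tuple[int, int]:
    """Representative pair whose separation is nearest the target."""
    k = int(np.argmin(np.abs(pairs.distance - target_mm)))
    return int(pairs.id_a[k]), int(pairs.id_b[k])


def run(config: RunConfig) -> dict:
    """Execute a full analysis run and write all result tables.

    Returns the manifest (also written to ``manifest.json``): config
    hash, seed, versions, per-stage timings and the output file list.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = []
    files = []

    def stage(name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        stages.append({"stage": name, "seconds": round(time.perf_counter() - t0, 4)})
        return result

    rec = stage("load", _load_input, config)

    for scheme in config.schemes:
        ref, pairs = stage(f"reference:{scheme}", apply_scheme, rec, scheme, config)
        coeffs = stage(
            f"spectral:{scheme}",
            spectral.spectral_coefficients,
            ref,
            config.window,
            config.taper,
        )
        psd = spectral.power_spectrum(coeffs)
        if config.rolloff:
            psd = spectral.rolloff_correction(psd)
        if config.mask_hz:
            psd = spectral.mask_frequencies(psd, config.mask_hz)

        psd_path = out_dir / f"psd_{scheme}.csv"
        psd.to_dataframe().to_csv(psd_path, index=False)
        files.append(psd_path.name)

        slopes = stage(
            f"slopes:{scheme}",
            spectral.slope_profiles,
            psd,
            config.slope_centers,
            config.slope_half_width,
        )
        slope_path = out_dir / f"slopes_{scheme}.csv"
        slopes.to_csv(slope_path, index=False)
        files.append(slope_path.name)

        pairs_path = out_dir / f"pairs_{scheme}.csv"
        pairs.to_csv(pairs_path)
        files.append(pairs_path.name)

        profile = stage(f"phase:{scheme}", phase_stats.pair_profiles, coeffs, pairs)
        profile_path = out_dir / f"pair_profiles_{scheme}.csv"
        profile.to_csv(profile_path, index=False)
        files.append(profile_path.name)
        logger.info(
            "scheme %s: %d electrodes, %d pairs", scheme, ref.n_electrodes, pairs.n_pairs
        )

    if config.flip_pair_distance is not None:
        flip_summary = stage("flip", _run_flip, rec, config)
        flip_path = out_dir / "flip_analysis.json"
        flip_path.write_text(json.dumps(flip_summary, indent=1))
        files.append(flip_path.name)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"lfpref": lfpref.__version__, "numpy": np.__version__},
        "stages": stages,
        "files": sorted(files),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _run_flip(rec: EpochedRecording, config: RunConfig) -> dict:
    """Flip analysis for a representative pair, per configured band."""
    coeffs = spectral.spectral_coefficients(rec, config.window, config.taper)
    pairs = geometry.unique_pairs(rec.grid, config.max_distance, config.bin_edges)
    id_a, id_b = _flip_pair(pairs, config.flip_pair_distance)
    raw = coeffs.single_taper()
    ref_coeff = raw.mean(axis=0)  # average-reference coefficient
    ia, ib = phase_stats.coeffs_index(coeffs, np.asarray([id_a, id_b]))
    out = {"pair": [id_a, id_b]}
    for f_lo, f_hi in config.bands:
        band = (coeffs.frequencies >= f_lo) & (coeffs.frequencies <= f_hi)
        flip = phase_stats.flip_analysis(
            raw[ia][:, band], raw[ib][:, band], ref_coeff[:, band]
        )
        out[f"{f_lo:g}-{f_hi:g}Hz"] = flip.summary()
    return out
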