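"""Electrode-grid bookkeeping for regular 2D microelectrode arrays.

Positions live on a lattice with spacing ``pitch`` (mm): the site at
(row, col) sits at ``(row * pitch, col * pitch)``, origin at the first
lattice site.  Three grid kinds exist:

* ``real`` — physical electrodes on lattice sites,
* ``bipolar-virtual`` — notional electrodes at the midpoint of a real
  electrode pair (the pair order is the subtraction order),
* ``csd`` — the subset of real electrodes with four good one-pitch
  neighbors, eligible for the CSD transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Absolute tolerance (mm) for lattice-distance comparisons.
DISTANCE_TOL = 1e-6

#: Default pitch of the array, mm.
DEFAULT_PITCH = 0.4

#: Default pair-distance cutoff, mm.
DEFAULT_MAX_DISTANCE = 4.0

#: Default reporting bins (lo, hi] in mm.
DEFAULT_BIN_EDGES = (0.0, 0.4, 1.2, 2.4, 4.0)

GRID_KINDS = ("real", "bipolar-virtual", "csd")

SHARED_KINDS = (
    "none",
    "bipolar-shared-electrode",
    "csd-adjacent",
    "csd-diagonal",
    "csd-two-pitch",
)


@dataclass(frozen=True)
class ElectrodeGrid:
    """A set of electrodes on (or derived from) a regular 2D lattice.

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice extent.
    pitch : float
        Lattice spacing in mm.
    good_mask : ndarray of bool, shape (n_rows, n_cols)
        Which lattice sites carry a usable electrode.  For virtual grids
        this is the mask of the parent real grid.
    electrode_ids : ndarray of int
        Stable identifiers.  Real/CSD grids use the lattice id
        ``row * n_cols + col``; virtual grids use sequential ids.
    positions : ndarray of float, shape (n, 2)
        (y, x) positions in mm, i.e. ``(row * pitch, col * pitch)`` for
        lattice sites, pair midpoints for virtual electrodes.
    kind : str
        One of ``real``, ``bipolar-virtual``, ``csd``.
    bipolar_pairs : ndarray of int, shape (n, 2), optional
        For virtual grids only: the (minuend, subtrahend) real ids.
    """

    n_rows: int
    n_cols: int
    pitch: float
    good_mask: np.ndarray
    electrode_ids: np.ndarray
    positions: np.ndarray
    kind: str = "real"
    bipolar_pairs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in GRID_KINDS:
            raise ValueError(f"unknown grid kind {self.kind!r}")
        if self.good_mask.shape != (self.n_rows, self.n_cols):
            raise ValueError("good_mask shape does not match lattice")
        if len(self.electrode_ids) == 0:
            raise ValueError("grid has no usable electrodes")
        if len(self.positions) != len(self.electrode_ids):
            raise ValueError("positions/ids length mismatch")
        if self.kind == "bipolar-virtual" and self.bipolar_pairs is None:
            raise ValueError("bipolar-virtual grid requires bipolar_pairs")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    @property
    def center(self) -> np.ndarray:
        """Centroid of the electrodes, mm."""
        return self.positions.mean(axis=0)

    def index_of(self, ids: np.ndarray) -> np.ndarray:
        """Map electrode ids to row indices into ``positions``/recordings."""
        ids = np.atleast_1d(np.asarray(ids, dtype=int))
        order = np.argsort(self.electrode_ids)
        pos = np.searchsorted(self.electrode_ids, ids, sorter=order)
        if np.any(pos >= len(order)):
            bad = ids[pos >= len(order)][0]
            raise KeyError(f"electrode id {bad} not in grid")
        idx = order[pos]
        missing = self.electrode_ids[idx] != ids
        if np.any(missing):
            raise KeyError(f"electrode id {ids[missing][0]} not in grid")
        return idx

    def lattice_site(self, electrode_id: int) -> tuple[int, int]:
        """(row, col) of a lattice electrode id."""
        return divmod(int(electrode_id), self.n_cols)


@dataclass
class PairTable:
    """Unique unordered electrode pairs with distances and artifact flags."""

    grid: ElectrodeGrid
    id_a: np.ndarray
    id_b: np.ndarray
    distance: np.ndarray
    bin_label: np.ndarray
    shared_component: np.ndarray
    shared_kind: np.ndarray
    bin_edges: tuple = field(default=DEFAULT_BIN_EDGES)

    @property
    def n_pairs(self) -> int:
        return len(self.id_a)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id_a": self.id_a,
                "id_b": self.id_b,
                "distance_mm": self.distance,
                "bin": self.bin_label,
                "shared_component": self.shared_component,
                "shared_kind": self.shared_kind,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def subset(self, mask: np.ndarray) -> "PairTable":
        return PairTable(
            grid=self.grid,
            id_a=self.id_a[mask],
            id_b=self.id_b[mask],
            distance=self.distance[mask],
            bin_label=self.bin_label[mask],
            shared_component=self.shared_component[mask],
            shared_kind=self.shared_kind[mask],
            bin_edges=self.bin_edges,
        )


def build_grid(
    n_rows: int,
    n_cols: int,
    pitch: float = DEFAULT_PITCH,
    good_mask: np.ndarray | None = None,
) -> ElectrodeGrid:
    """Build a real electrode grid on an ``n_rows x n_cols`` lattice.

    ``good_mask`` defaults to all-good.  Raises ``ValueError`` when the
    mask leaves no usable electrode.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice must be at least 1 x 1")
    if good_mask is None:
        good_mask = np.ones((n_rows, n_cols), dtype=bool)
    good_mask = np.asarray(good_mask, dtype=bool)
    if good_mask.shape != (n_rows, n_cols):
        raise ValueError("good_mask shape does not match lattice")
    if not good_mask.any():
        raise ValueError("good_mask leaves no usable electrodes")
    rows, cols = np.nonzero(good_mask)
    ids = rows * n_cols + cols
    positions = np.column_stack([rows, cols]).astype(float) * pitch
    return ElectrodeGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        pitch=pitch,
        good_mask=good_mask,
        electrode_ids=ids,
        positions=positions,
        kind="real",
    )


def assign_distance_bins(
    distances: np.ndarray, bin_edges: tuple = DEFAULT_BIN_EDGES
) -> np.ndarray:
    """Label distances with half-open bins (lo, hi], tolerance-aware.

    Distances beyond the last edge get the empty label ``""``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    labels = np.zeros(len(distances), dtype="<U24")
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (distances > lo + DISTANCE_TOL) & (distances <= hi + DISTANCE_TOL)
        labels[mask] = f"({lo:g}, {hi:g}]"
    return labels


def unique_pairs(
    grid: ElectrodeGrid,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    bin_edges: tuple = DEFAULT_BIN_EDGES,
) -> PairTable:
    """All unique unordered electrode pairs within ``max_distance`` mm.

    Of the two ordered pairs (a, b) and (b, a) only the one with
    ``id_a < id_b`` is kept; pairs farther apart than the cutoff are
    discarded.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    n = grid.n_electrodes
    if n < 2:
        raise ValueError("need at least 2 electrodes to form pairs")
    ia, ib = np.triu_indices(n, k=1)
    d = np.linalg.norm(grid.positions[ia] - grid.positions[ib], axis=1)
    keep = d <= max_distance + DISTANCE_TOL
    ia, ib, d = ia[keep], ib[keep], d[keep]
    return PairTable(
        grid=grid,
        id_a=grid.electrode_ids[ia],
        id_b=grid.electrode_ids[ib],
        distance=d,
        bin_label=assign_distance_bins(d, bin_edges),
        shared_component=np.zeros(len(d), dtype=bool),
        shared_kind=np.full(len(d), "none", dtype="<U24"),
        bin_edges=bin_edges,
    )


def _neighbor_sites(grid: ElectrodeGrid, row: int, col: int) -> list[tuple[int, int]]:
    return [(row - 1, col), (row + 1, col), (row, col - 1), (row, col + 1)]


def csd_eligible(grid: ElectrodeGrid) -> np.ndarray:
    """Ids of good electrodes whose four one-pitch neighbors are all good.

    Electrodes on the lattice boundary are never eligible.
    """
    if grid.kind != "real":
        raise ValueError("CSD eligibility is defined on real grids")
    eligible = []
    for eid in grid.electrode_ids:
        row, col = grid.lattice_site(eid)
        ok = True
        for r, c in _neighbor_sites(grid, row, col):
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                ok = False
                break
            if not grid.good_mask[r, c]:
                ok = False
                break
        if ok:
            eligible.append(int(eid))
    return np.asarray(eligible, dtype=int)


def csd_grid(grid: ElectrodeGrid) -> ElectrodeGrid:
    """Restrict a real grid to its CSD-eligible electrodes (kind=csd)."""
    ids = csd_eligible(grid)
    if len(ids) == 0:
        raise ValueError("no CSD-eligible electrodes on this grid")
    idx = grid.index_of(ids)
    return ElectrodeGrid(
        n_rows=grid.n_rows,
        n_cols=grid.n_cols,
        pitch=grid.pitch,
        good_mask=grid.good_mask,
        electrode_ids=ids,
        positions=grid.positions[idx],
        kind="csd",
    )


def bipolar_virtual_grid(
    grid: ElectrodeGrid,
    scheme: str = "center-out",
    max_distance: float = DEFAULT_MAX_DISTANCE,
    restricted: bool = False,
    bin_edges: tuple = DEFAULT_BIN_EDGES,
    include_pairs: bool = True,
) -> tuple[ElectrodeGrid, PairTable | None]:
    """Construct virtual bipolar electrodes from real electrode pairs.

    One virtual electrode is created per retained real pair, positioned
    at the pair midpoint.  The stored pair order is the subtraction
    order (minuend, subtrahend):

    * ``center-out`` — the minuend is the electrode nearer the grid
      centroid (the farther signal is subtracted from the nearer one);
      ties broken by lower electrode id.
    * ``fixed-direction`` — the minuend is the electrode with the
      larger (row, col), i.e. lateral/dorsal subtracted from
      medial/ventral.

    When ``restricted`` is true a greedy maximal matching (pairs sorted
    by distance, then ids) ensures each real electrode is used at most
    once.

    Returns the virtual grid and the flagged pair table over the
    virtual electrodes (``None`` when ``include_pairs`` is false; the
    table grows quadratically in the number of virtual electrodes).
    """
    if scheme not in ("center-out", "fixed-direction"):
        raise ValueError(f"unknown bipolar scheme {scheme!r}")
    if grid.kind != "real":
        raise ValueError("bipolar virtual grid is built from a real grid")
    real_pairs = unique_pairs(grid, max_distance=max_distance, bin_edges=bin_edges)

    order = np.lexsort((real_pairs.id_b, real_pairs.id_a, real_pairs.distance))
    ids_a = real_pairs.id_a[order]
    ids_b = real_pairs.id_b[order]

    if restricted:
        used: set[int] = set()
        keep = []
        for k, (a, b) in enumerate(zip(ids_a, ids_b)):
            if a in used or b in used:
                continue
            used.add(int(a))
            used.add(int(b))
            keep.append(k)
        ids_a, ids_b = ids_a[keep], ids_b[keep]

    center = grid.center
    if scheme == "center-out":
        da = np.linalg.norm(grid.positions[grid.index_of(ids_a)] - center, axis=1)
        db = np.linalg.norm(grid.positions[grid.index_of(ids_b)] - center, axis=1)
        tie = np.abs(da - db) <= DISTANCE_TOL
        a_first = (da < db) | (tie & (ids_a < ids_b))
    else:  # fixed-direction: subtract the site with larger (row, col)
        a_first = ids_a < ids_b
    minuend = np.where(a_first, ids_a, ids_b)
    subtrahend = np.where(a_first, ids_b, ids_a)

    idx_min = grid.index_of(minuend)
    idx_sub = grid.index_of(subtrahend)
    midpoints = 0.5 * (grid.positions[idx_min] + grid.positions[idx_sub])

    virtual = ElectrodeGrid(
        n_rows=grid.n_rows,
        n_cols=grid.n_cols,
        pitch=grid.pitch,
        good_mask=grid.good_mask,
        electrode_ids=np.arange(len(minuend)),
        positions=midpoints,
        kind="bipolar-virtual",
        bipolar_pairs=np.column_stack([minuend, subtrahend]),
    )
    if not include_pairs:
        return virtual, None
    if virtual.n_electrodes >= 2:
        vpairs = unique_pairs(virtual, max_distance=max_distance, bin_edges=bin_edges)
        vpairs = flag_shared_components(vpairs, "bipolar")
    else:
        vpairs = PairTable(
            grid=virtual,
            id_a=np.empty(0, dtype=int),
            id_b=np.empty(0, dtype=int),
            distance=np.empty(0),
            bin_label=np.empty(0, dtype="<U24"),
            shared_component=np.empty(0, dtype=bool),
            shared_kind=np.empty(0, dtype="<U24"),
            bin_edges=bin_edges,
        )
    return virtual, vpairs


def _csd_term_set(grid: ElectrodeGrid, electrode_id: int) -> frozenset[int]:
    """Real-electrode ids entering the CSD expression at one electrode."""
    row, col = grid.lattice_site(electrode_id)
    terms = {int(electrode_id)}
    for r, c in _neighbor_sites(grid, row, col):
        terms.add(r * grid.n_cols + c)
    return frozenset(terms)


def flag_shared_components(pairs: PairTable, scheme: str) -> PairTable:
    """Mark pairs whose referenced signals contain a common real term.

    Bipolar: true iff the two virtual electrodes' real-electrode sets
    intersect.  CSD: true iff the pair distance is one pitch
    (each CSD contains the other's center, phase difference pi),
    sqrt(2) pitch (two shared neighbors) or two pitches (one shared
    neighbor), checked against the actual term sets on the grid.
    """
    grid = pairs.grid
    if scheme == "bipolar":
        if grid.kind != "bipolar-virtual":
            raise ValueError("bipolar shared-component flags need a virtual grid")
        idx_a = grid.index_of(pairs.id_a)
        idx_b = grid.index_of(pairs.id_b)
        a_min = grid.bipolar_pairs[idx_a, 0]
        a_sub = grid.bipolar_pairs[idx_a, 1]
        b_min = grid.bipolar_pairs[idx_b, 0]
        b_sub = grid.bipolar_pairs[idx_b, 1]
        shared = (
            (a_min == b_min)
            | (a_min == b_sub)
            | (a_sub == b_min)
            | (a_sub == b_sub)
        )
        kind = np.where(shared, "bipolar-shared-electrode", "none").astype("<U24")
    elif scheme == "csd":
        if grid.kind != "csd":
            raise ValueError("csd shared-component flags need a csd grid")
        pitch = grid.pitch
        shared = np.zeros(pairs.n_pairs, dtype=bool)
        kind = np.full(pairs.n_pairs, "none", dtype="<U24")
        labels = {
            1.0: "csd-adjacent",
            np.sqrt(2.0): "csd-diagonal",
            2.0: "csd-two-pitch",
        }
        for k in range(pairs.n_pairs):
            d = pairs.distance[k] / pitch
            match = None
            for mult, lab in labels.items():
                if abs(d - mult) <= DISTANCE_TOL / pitch:
                    match = lab
                    break
            if match is None:
                continue
            terms_a = _csd_term_set(grid, pairs.id_a[k])
            terms_b = _csd_term_set(grid, pairs.id_b[k])
            if terms_a & terms_b:
                shared[k] = True
                kind[k] = match
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    return replace(pairs, shared_component=shared, shared_kind=kind)
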