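"""Vertex-wise functional connectivity.

Pearson correlation matrices per run, Fisher r-to-z transform, averaging
across runs into a stable mean z matrix, seed-map extraction,
discovery/replication test-retest correlation, and reliability-based
disattenuation of seed maps in dropout-affected cortex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import SurfaceMesh
from .simulate import SessionTimeseries

#: Fisher-z ceiling used for r = 1 (self-correlation sentinel).
R_CLIP = 1.0 - 1e-7
Z_SENTINEL = float(np.arctanh(R_CLIP))

#: Dense vertex budget: full VxV matrices above this are refused.
MAX_DENSE_VERTICES = 20_000

#: Default display range for seed maps, matching the published colorbar.
SEED_MAP_DISPLAY_RANGE = (0.2, 0.6)


class ResolutionGuardError(MemoryError):
    """Refusing to materialize a dense matrix beyond the vertex budget."""


@dataclass
class ZConnectivity:
    """Vertex x vertex Fisher-z connectivity, per run or run-averaged."""

    z: np.ndarray                  # (V, V) float64, symmetric
    n_runs_averaged: int
    dataset_label: str             # 'discovery' | 'replication' | 'full'
    mask: np.ndarray | None = None  # (V,) bool, True = invalid vertex

    @property
    def n_vertices(self) -> int:
        return self.z.shape[0]


@dataclass
class FCMap:
    """Seed functional-connectivity map (one z per vertex)."""

    seed_vertex: int
    values: np.ndarray
    dataset_label: str
    display_range: tuple[float, float] = SEED_MAP_DISPLAY_RANGE


@dataclass
class ReliabilityMap:
    values: np.ndarray             # (V,) in [0, 1]
    n_runs: int


def zero_variance_mask(ts: SessionTimeseries) -> np.ndarray:
    return ts.data.std(axis=1) == 0


def corr_matrix(ts: SessionTimeseries) -> np.ndarray:
    """Full Pearson correlation matrix of the vertex time series.

    Zero-variance vertices get nan rows/columns (they are recorded in
    the mask carried by :func:`mean_z_matrix`).
    """
    if ts.n_vertices > MAX_DENSE_VERTICES:
        raise ResolutionGuardError(
            f"{ts.n_vertices} vertices exceeds the dense budget "
            f"({MAX_DENSE_VERTICES}); use mean_z_rows for streamed seed rows"
        )
    bad = zero_variance_mask(ts)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts.data)
    r = np.clip(r, -1.0, 1.0)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    return r


def fisher_z(r) -> np.ndarray | float:
    """Fisher r-to-z: atanh with |r| clipped just below 1.

    Odd in r; |r| > 1 is rejected.
    """
    arr = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmax(np.abs(arr), initial=0.0) > 1.0 + 1e-12:
            raise ValueError("|r| > 1 passed to fisher_z")
    out = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return float(out) if np.isscalar(r) else out


def _sorted_runs(runs: list[SessionTimeseries]) -> list[SessionTimeseries]:
    # canonical (subject, run) order makes averaging bit-identical under
    # permutations of the input list
    return sorted(runs, key=lambda ts: (ts.subject_id, ts.run_id))


def mean_z_matrix(runs: list[SessionTimeseries],
                  dataset_label: str = "full") -> ZConnectivity:
    """Average the per-run Fisher-z matrices elementwise.

    Runs are summed in canonical (subject, run_id) order so the result
    is bit-identical regardless of input ordering.  The diagonal holds
    the z sentinel for r = 1; vertices with zero variance in any run are
    masked.
    """
    if not runs:
        raise ValueError("need at least one run")
    v = runs[0].n_vertices
    if any(ts.n_vertices != v for ts in runs):
        raise ValueError("runs have mismatching vertex dimensions")
    acc = np.zeros((v, v))
    mask = np.zeros(v, dtype=bool)
    for ts in _sorted_runs(runs):
        r = corr_matrix(ts)
        mask |= np.isnan(r).all(axis=1)
        acc += np.nan_to_num(fisher_z(r))
    z = acc / len(runs)
    z[mask, :] = np.nan
    z[:, mask] = np.nan
    np.fill_diagonal(z, Z_SENTINEL)
    return ZConnectivity(z=z, n_runs_averaged=len(runs),
                         dataset_label=dataset_label, mask=mask)


def mean_z_rows(runs: list[SessionTimeseries], rows: np.ndarray,
                dataset_label: str = "full") -> np.ndarray:
    """Run-averaged z for selected seed rows only (no dense matrix).

    Memory-safe path for high-resolution meshes: computes the
    rows x all-vertices block of the mean z matrix.
    """
    rows = np.asarray(rows, dtype=int)
    v = runs[0].n_vertices
    acc = np.zeros((len(rows), v))
    for ts in _sorted_runs(runs):
        x = ts.data - ts.data.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        sd_safe = np.where(sd == 0, 1.0, sd)
        xn = x / sd_safe[:, None]
        r = (xn[rows] @ xn.T) / ts.n_frames
        r = np.clip(r, -1.0, 1.0)
        r[:, sd == 0] = np.nan
        r[sd[rows] == 0, :] = np.nan
        acc += np.nan_to_num(fisher_z(r))
    z = acc / len(runs)
    for i, s in enumerate(rows):
        z[i, s] = Z_SENTINEL
    return z


class _RowDict:
    """Sparse row access with the ``z[i] -> row`` interface."""

    def __init__(self, rows: dict[int, np.ndarray]):
        self._rows = rows

    def __getitem__(self, i: int) -> np.ndarray:
        return self._rows[int(i)]


@dataclass
class ZRowView:
    """Row-subset view of a mean z matrix (duck-types ZConnectivity).

    Holds only the seed rows needed by seed search and region selection,
    so high-resolution meshes never materialize a dense VxV matrix.
    """

    z: _RowDict
    n_vertices: int
    n_runs_averaged: int
    dataset_label: str
    mask: np.ndarray | None = None


def mean_z_row_view(runs: list[SessionTimeseries], rows: np.ndarray,
                    dataset_label: str = "full") -> ZRowView:
    """Run-averaged z restricted to ``rows``, as a ZConnectivity stand-in."""
    rows = np.asarray(rows, dtype=int)
    block = mean_z_rows(runs, rows, dataset_label)
    return ZRowView(z=_RowDict({int(r): block[i] for i, r in enumerate(rows)}),
                    n_vertices=runs[0].n_vertices,
                    n_runs_averaged=len(runs), dataset_label=dataset_label)


def seed_map(z: ZConnectivity, seed_vertex: int) -> FCMap:
    """Extract one seed's FC map (a row of the z matrix)."""
    if not (0 <= seed_vertex < z.n_vertices):
        raise IndexError(f"seed vertex {seed_vertex} out of range")
    return FCMap(seed_vertex=int(seed_vertex), values=z.z[seed_vertex].copy(),
                 dataset_label=z.dataset_label)


def test_retest(za: ZConnectivity, zb: ZConnectivity) -> float:
    """Pearson r between two mean z matrices (upper triangles).

    The diagonal sentinel and masked vertices are excluded; used to
    correlate the discovery- and replication-half matrices.
    """
    if za.z.shape != zb.z.shape:
        raise ValueError("matrices have different dimensions")
    v = za.n_vertices
    iu = np.triu_indices(v, k=1)
    a, b = za.z[iu], zb.z[iu]
    good = np.isfinite(a) & np.isfinite(b)
    if not good.any():
        raise ValueError("no valid entries to correlate (all masked)")
    return float(np.corrcoef(a[good], b[good])[0, 1])


def _icc_1_1(x: np.ndarray) -> float:
    """One-way random-effects ICC(1,1); x is (runs, items)."""
    k, n = x.shape
    item_mean = x.mean(axis=0)
    grand = x.mean()
    msb = k * np.sum((item_mean - grand) ** 2) / max(n - 1, 1)
    msw = np.sum((x - item_mean[None, :]) ** 2) / max(n * (k - 1), 1)
    if msb == 0 and msw == 0:
        return 1.0  # constant, perfectly reproduced
    denom = msb + (k - 1) * msw
    if denom == 0:
        return 0.0
    return float((msb - msw) / denom)


def reliability_map(per_run_maps: list[FCMap], mesh: SurfaceMesh) -> ReliabilityMap:
    """Across-run reliability of a seed's FC map, per vertex.

    Operationalized as ICC(1,1) with runs as raters and the vertex plus
    its 1-hop neighbors as items, clipped to [0, 1].  This is a declared
    stand-in for the (uncited-formula) reliability-based dropout
    estimate; see the methods note.
    """
    if len(per_run_maps) < 3:
        raise ValueError("reliability needs >= 3 runs")
    seeds = {m.seed_vertex for m in per_run_maps}
    if len(seeds) != 1:
        raise ValueError("per-run maps must share one seed vertex")
    stack = np.vstack([m.values for m in per_run_maps])  # (runs, V)
    v = stack.shape[1]
    adj = mesh.adjacency()
    values = np.zeros(v)
    for vert in range(v):
        items = np.concatenate(([vert], adj.indices[adj.indptr[vert]: adj.indptr[vert + 1]]))
        sub = stack[:, items]
        if not np.isfinite(sub).all():
            values[vert] = np.nan
            continue
        values[vert] = np.clip(_icc_1_1(sub), 0.0, 1.0)
    return ReliabilityMap(values=values, n_runs=len(per_run_maps))


def disattenuate(fc: FCMap, rel: ReliabilityMap, floor: float = 0.04) -> FCMap:
    """Classical correction for attenuation: z' = z / sqrt(max(rel, floor))."""
    if not (0.0 < floor <= 1.0):
        raise ValueError("floor must lie in (0, 1]")
    if fc.values.shape != rel.values.shape:
        raise ValueError("map and reliability are in different vertex spaces")
    divisor = np.sqrt(np.maximum(rel.values, floor))
    return FCMap(seed_vertex=fc.seed_vertex, values=fc.values / divisor,
                 dataset_label=fc.dataset_label, display_range=fc.display_range)
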