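"""Planted interdigitated network templates.

Ground truth for the simulation: a small number of distributed networks,
each owning one parcel per cortical "zone", with parcels of different
networks lying side by side inside every zone (the interdigitated
arrangement the analysis is designed to detect).  Per-subject spatial
jitter displaces parcel anchors by a few mesh hops, emulating the
idiosyncratic region positions that defeat between-subject alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .mesh import SurfaceMesh


class PlacementError(RuntimeError):
    """Zones or parcels cannot be placed disjointly on the mesh."""


@dataclass
class NetworkTemplate:
    """Vertex -> network assignment with per-zone parcel layout.

    ``assignment`` uses 0 for background and 1..n_networks for planted
    networks.  ``anchors[zone][net]`` is the parcel anchor vertex of
    network ``net`` (1-based id) in ``zone``; ``jitter_record`` holds the
    hop displacement applied to each anchor for this subject.
    """

    assignment: np.ndarray                 # (V,) int64
    n_networks: int
    zones: list[int]
    zone_label: np.ndarray                 # (V,) int64, -1 outside zones
    anchors: dict[int, dict[int, int]]
    jitter_record: dict[tuple[int, int], int] = field(default_factory=dict)
    subject_seed: int | None = None

    def support(self, net: int) -> np.ndarray:
        """Vertex indices belonging to network ``net`` (1-based)."""
        return np.flatnonzero(self.assignment == net)

    def parcel(self, zone: int, net: int) -> np.ndarray:
        """Vertices of network ``net``'s parcel inside ``zone``."""
        return np.flatnonzero((self.assignment == net) & (self.zone_label == zone))


def choose_zone_anchors(mesh: SurfaceMesh, n_zones: int, zone_radius: int) -> np.ndarray:
    """Deterministic well-separated zone anchors by farthest-point sampling.

    Starts at vertex 0 and greedily adds the vertex maximizing the
    minimum hop distance to all chosen anchors (the disconnected other
    hemisphere counts as infinitely far, so zones spread over both).
    Raises :class:`PlacementError` if the resulting geodesic discs of
    radius ``zone_radius`` would overlap.
    """
    anchors = [0]
    dmin = mesh.hop_distance(0)
    for _ in range(n_zones - 1):
        nxt = int(np.argmax(np.where(np.isinf(dmin), mesh.n_vertices + 1.0, dmin)))
        # prefer the other hemisphere while it is untouched
        inf_mask = np.isinf(dmin)
        if inf_mask.any():
            nxt = int(np.flatnonzero(inf_mask)[0])
        anchors.append(nxt)
        dmin = np.minimum(dmin, mesh.hop_distance(nxt))
    anchors = np.asarray(anchors, dtype=np.int64)
    d = mesh.hop_distance(anchors)
    pair = d[:, anchors]
    np.fill_diagonal(pair, np.inf)
    if np.nanmin(pair) <= 2 * zone_radius:
        raise PlacementError(
            f"{n_zones} zones of radius {zone_radius} do not fit disjointly "
            f"on a level-{mesh.level} mesh (closest anchors {np.nanmin(pair):.0f} hops apart)"
        )
    return anchors


def _zone_distance(mesh: SurfaceMesh, zone_vertices: np.ndarray,
                   sources: np.ndarray) -> np.ndarray:
    """Hop distances restricted to the zone subgraph."""
    sub = mesh.adjacency()[zone_vertices][:, zone_vertices]
    src_local = np.searchsorted(zone_vertices, sources)
    return dijkstra(sub, unweighted=True, indices=src_local)


def plant_networks(
    mesh: SurfaceMesh,
    n_networks: int = 2,
    n_zones: int = 6,
    parcel_radius: int = 2,
    jitter_steps: int = 0,
    subject_seed: int = 0,
    zone_radius: int | None = None,
) -> NetworkTemplate:
    """Plant ``n_networks`` disjoint networks with one parcel per zone.

    Zones are geodesic discs around well-separated anchors.  Inside each
    zone the parcel anchors of the networks are mutually adjacent
    vertices; each zone vertex joins the parcel of its nearest anchor if
    within ``parcel_radius`` hops (ties favor the lower network id), so
    parcels are disjoint by construction and share borders.

    With ``jitter_steps > 0`` every parcel anchor performs a random walk
    of ``jitter_steps`` hops inside its zone (seeded per subject),
    rejecting moves that would collide with another network's anchor;
    with ``jitter_steps = 0`` no randomness is consumed and the template
    is identical for every ``subject_seed``.
    """
    if zone_radius is None:
        zone_radius = parcel_radius + max(jitter_steps, 1) + 1
    zone_anchor = choose_zone_anchors(mesh, n_zones, zone_radius)

    zone_label = np.full(mesh.n_vertices, -1, dtype=np.int64)
    for z, a in enumerate(zone_anchor):
        zone_label[mesh.geodesic_disc(int(a), zone_radius)] = z

    rng = np.random.default_rng(np.random.SeedSequence([subject_seed, 0xD15C]))
    assignment = np.full(mesh.n_vertices, 0, dtype=np.int64)
    anchors: dict[int, dict[int, int]] = {}
    jitter_record: dict[tuple[int, int], int] = {}

    for z, za in enumerate(zone_anchor):
        zone_verts = np.flatnonzero(zone_label == z)
        # base parcel anchors: the zone anchor plus its lowest-index neighbors
        nbrs = np.sort(mesh.neighbors(int(za)))
        base = [int(za)] + [int(v) for v in nbrs[: n_networks - 1]]
        if len(base) < n_networks:
            raise PlacementError(f"zone {z} cannot host {n_networks} adjacent parcel anchors")
        placed: dict[int, int] = {}
        for net in range(1, n_networks + 1):
            a = base[net - 1]
            moved = 0
            if jitter_steps > 0:
                zone_set = set(int(v) for v in zone_verts)
                for attempt in range(20):
                    cand, steps = a, 0
                    for _ in range(jitter_steps):
                        opts = [int(v) for v in mesh.neighbors(cand) if int(v) in zone_set]
                        if not opts:
                            break
                        cand = int(rng.choice(opts))
                        steps += 1
                    if cand not in placed.values():
                        a, moved = cand, steps
                        break
            if a in placed.values():
                raise PlacementError(f"could not place anchor of network {net} in zone {z}")
            placed[net] = a
            jitter_record[(z, net)] = moved
        anchors[z] = placed

        src = np.asarray(sorted(placed.values()), dtype=np.int64)
        order = np.argsort([placed[n] for n in sorted(placed)])  # net for each src row
        nets_for_src = np.array(sorted(placed, key=placed.get))
        dz = _zone_distance(mesh, zone_verts, src)
        within = dz <= parcel_radius
        dz = np.where(within, dz, np.inf)
        best = np.argmin(dz, axis=0)
        reached = np.isfinite(dz[best, np.arange(len(zone_verts))])
        # ties: argmin picks the first row; rows are anchor-sorted, so break
        # ties explicitly in favor of the lower network id
        dmin = dz[best, np.arange(len(zone_verts))]
        for i in np.flatnonzero(reached):
            tied = np.flatnonzero(dz[:, i] == dmin[i])
            net = int(min(nets_for_src[tied]))
            assignment[zone_verts[i]] = net
        del order

    return NetworkTemplate(
        assignment=assignment, n_networks=n_networks,
        zones=list(range(n_zones)), zone_label=zone_label,
        anchors=anchors, jitter_record=jitter_record, subject_seed=subject_seed,
    )
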