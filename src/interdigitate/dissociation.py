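"""Hypothesis testing: the 2x2 ANOVA double-dissociation battery.

A priori regions (single vertices) are fixed on the discovery half of
the data: one seed pair in the search zone and, per distributed test
zone, one target vertex for each network chosen to maximize the
separation of the two seed maps.  On the held-out replication sessions,
each session contributes one Fisher-z correlation per (seed, target)
cell, giving a balanced 2x2 design with as many observations per cell as
replication sessions.  Significant crossover interactions across zones
and subjects constitute the double dissociation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .connectivity import ZConnectivity, fisher_z
from .simulate import SessionTimeseries, StudyDataset


class ProvenanceError(ValueError):
    """Discovery/replication firewall violation."""


@dataclass
class RegionSet:
    """Per-subject a priori vertices: a seed pair plus per-zone targets.

    ``zone_targets`` maps a zone name/id to the (network A, network B)
    target vertices.  A lone region assigned to only one network (the
    parahippocampal case) is expressed by pairing it with the opposite
    network's region from a designated partner zone, producing an
    ordinary 2x2 entry.
    """

    subject_id: int
    seed_a: int
    seed_b: int
    zone_targets: dict[object, tuple[int, int]]
    provenance: str = "discovery"

    def __post_init__(self) -> None:
        verts = [self.seed_a, self.seed_b]
        for a, b in self.zone_targets.values():
            verts += [a, b]
        if len(set(verts)) != len(verts):
            raise ValueError("region vertices must be pairwise distinct")

    def region_list(self) -> list[tuple[str, object, int]]:
        """Ordered (network, zone, vertex) triples: seeds then targets."""
        out = [("A", "seed", self.seed_a), ("B", "seed", self.seed_b)]
        for zone, (a, b) in self.zone_targets.items():
            out.append(("A", zone, a))
            out.append(("B", zone, b))
        return out


@dataclass
class AnovaResult:
    zone: object
    subject_id: int
    cell_means: np.ndarray      # 2x2, rows = seed (A,B), cols = target (A,B)
    cell_sem: np.ndarray
    F_seed: float
    F_target: float
    F_interaction: float
    df: tuple[int, int]
    p_interaction: float
    crossover_class: str
    n_per_cell: int


@dataclass
class DissociationReport:
    results: list[AnovaResult]
    alpha: float
    n_significant: int
    n_crossover: int
    null_expectation: float      # expected false positives at alpha
    dataset_labels: tuple[str, str] = ("discovery", "replication")

    @property
    def n_tests(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "subject": r.subject_id, "zone": r.zone,
                "mean_AA": r.cell_means[0, 0], "mean_AB": r.cell_means[0, 1],
                "mean_BA": r.cell_means[1, 0], "mean_BB": r.cell_means[1, 1],
                "F_seed": r.F_seed, "F_target": r.F_target,
                "F_interaction": r.F_interaction,
                "df1": r.df[0], "df2": r.df[1],
                "p_interaction": r.p_interaction,
                "crossover_class": r.crossover_class,
                "n_per_cell": r.n_per_cell,
            })
        return pd.DataFrame(rows)


def select_regions(z: ZConnectivity, seed_a: int, seed_b: int,
                   zone_label: np.ndarray, test_zones: list[int],
                   subject_id: int = 0) -> RegionSet:
    """Pick per-zone target vertices that maximize network separation.

    Using discovery-half connectivity only: in each test zone the
    network-A target is the vertex maximizing z(seed_a) - z(seed_b) and
    vice versa (distinct vertices enforced).  The z matrix must carry
    the 'discovery' label — targets may never be chosen on replication
    data.
    """
    if z.dataset_label != "discovery":
        raise ProvenanceError(
            f"regions must be selected on discovery data, got '{z.dataset_label}'"
        )
    row_a, row_b = z.z[seed_a].copy(), z.z[seed_b].copy()
    for row in (row_a, row_b):
        row[[seed_a, seed_b]] = np.nan
        if z.mask is not None:
            row[z.mask] = np.nan
    targets: dict[object, tuple[int, int]] = {}
    for zone in test_zones:
        verts = np.flatnonzero(zone_label == zone)
        if len(verts) < 2:
            raise ValueError(f"test zone {zone} has fewer than 2 usable vertices")
        sep = row_a[verts] - row_b[verts]
        ta = verts[int(np.nanargmax(sep))]
        order = np.argsort(sep)  # ascending sep = descending B-separation; nan last
        tb = None
        for i in order:
            if verts[i] != ta:
                tb = verts[i]
                break
        targets[zone] = (int(ta), int(tb))
    return RegionSet(subject_id=subject_id, seed_a=seed_a, seed_b=seed_b,
                     zone_targets=targets)


def extract_cell_values(sessions: list[SessionTimeseries],
                        regions: RegionSet) -> pd.DataFrame:
    """Per-session Fisher-z between each seed and each zone target.

    ``sessions`` must all be replication runs (even session ids): the
    firewall rejects any overlap with the discovery half the regions
    were defined on.  Returns a tidy frame with one row per
    (session, zone, seed network, target network).
    """
    if regions.provenance != "discovery":
        raise ProvenanceError(
            f"region set provenance is '{regions.provenance}', not 'discovery'"
        )
    for ts in sessions:
        if StudyDataset.dataset_label(ts.run_id) != "replication":
            raise ProvenanceError(
                f"session {ts.run_id} is a discovery run; the battery may "
                "only use replication sessions"
            )
    rows = []
    seeds = {"A": regions.seed_a, "B": regions.seed_b}
    for ts in sessions:
        x = ts.data - ts.data.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        for zone, (ta, tb) in regions.zone_targets.items():
            for snet, sv in seeds.items():
                for tnet, tv in (("A", ta), ("B", tb)):
                    if sv == tv:
                        raise ValueError("seed and target vertices coincide")
                    if sd[sv] == 0 or sd[tv] == 0:
                        raise ValueError(
                            f"zero-variance region vertex in session {ts.run_id}"
                        )
                    r = float(np.dot(x[sv], x[tv]) / (ts.n_frames * sd[sv] * sd[tv]))
                    rows.append({"session": ts.run_id, "zone": zone,
                                 "seed_net": snet, "target_net": tnet,
                                 "z": fisher_z(np.clip(r, -1.0, 1.0))})
    return pd.DataFrame(rows)


def anova_2x2(cells: np.ndarray) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    ``cells`` has shape (2, 2, n): seed factor x target factor x
    observations.  Classical sums-of-squares decomposition; each F has
    (1, 4(n-1)) degrees of freedom and p comes from the F distribution.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3 or cells.shape[:2] != (2, 2):
        raise ValueError("cells must have shape (2, 2, n)")
    n = cells.shape[2]
    if n < 2:
        raise ValueError("need >= 2 observations per cell")
    grand = cells.mean()
    cell_means = cells.mean(axis=2)
    row_means = cells.mean(axis=(1, 2))
    col_means = cells.mean(axis=(0, 2))

    ss_row = 2 * n * np.sum((row_means - grand) ** 2)
    ss_col = 2 * n * np.sum((col_means - grand) ** 2)
    ss_inter = n * np.sum(
        (cell_means - row_means[:, None] - col_means[None, :] + grand) ** 2
    )
    ss_within = np.sum((cells - cell_means[:, :, None]) ** 2)
    df_err = 4 * (n - 1)
    ms_within = ss_within / df_err
    if ms_within == 0:
        # zero within-cell variance: effects below float round-off of the
        # grand mean count as exactly null
        tol = n * (np.abs(grand) + 1.0) ** 2 * np.finfo(float).eps ** 2 * 16
        null = ss_inter <= tol
        f_row = f_col = f_int = 0.0 if null else np.inf
        p = 1.0 if null else 0.0
    else:
        f_row = ss_row / ms_within
        f_col = ss_col / ms_within
        f_int = ss_inter / ms_within
        p = float(scipy.stats.f.sf(f_int, 1, df_err))
    return AnovaResult(
        zone=None, subject_id=-1, cell_means=cell_means,
        cell_sem=cells.std(axis=2, ddof=1) / np.sqrt(n),
        F_seed=float(f_row), F_target=float(f_col), F_interaction=float(f_int),
        df=(1, df_err), p_interaction=max(p, np.finfo(float).tiny),
        crossover_class=classify_crossover(cell_means), n_per_cell=n,
    )


def classify_crossover(cell_means: np.ndarray) -> str:
    """Classify a 2x2 pattern of means.

    'crossover' iff mean(A->A) > mean(A->B) and mean(B->B) > mean(B->A);
    'ordinal' iff the interaction contrast AA - AB - BA + BB is positive
    but one of the two inequalities fails; 'none' otherwise (including
    exact ties).
    """
    m = np.asarray(cell_means, dtype=float)
    aa, ab, ba, bb = m[0, 0], m[0, 1], m[1, 0], m[1, 1]
    if aa > ab and bb > ba:
        return "crossover"
    if (aa - ab - ba + bb) > 0:
        return "ordinal"
    return "none"


def run_battery(study: StudyDataset, regions_by_subject: dict[int, RegionSet],
                alpha: float = 0.01) -> DissociationReport:
    """One 2x2 ANOVA per subject x zone on replication sessions.

    No multiple-testing correction is applied across tests — the design
    argues by convergence of repeated significant results — but the
    report carries the family-wise expectation under the null for
    transparency.
    """
    results: list[AnovaResult] = []
    for subject in study.subject_ids:
        if subject not in regions_by_subject:
            raise ValueError(f"missing region set for subject {subject}")
        regions = regions_by_subject[subject]
        sessions = study.replication(subject)
        table = extract_cell_values(sessions, regions)
        for zone in regions.zone_targets:
            sub = table[table.zone == zone]
            cells = np.empty((2, 2, sub.session.nunique()))
            for i, snet in enumerate("AB"):
                for j, tnet in enumerate("AB"):
                    vals = sub[(sub.seed_net == snet) & (sub.target_net == tnet)]
                    cells[i, j] = vals.sort_values("session")["z"].to_numpy()
            res = anova_2x2(cells)
            res.zone = zone
            res.subject_id = subject
            results.append(res)
    n_sig = sum(r.p_interaction < alpha for r in results)
    n_cross = sum(r.crossover_class == "crossover" for r in results)
    return DissociationReport(results=results, alpha=alpha,
                              n_significant=n_sig, n_crossover=n_cross,
                              null_expectation=alpha * len(results))
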