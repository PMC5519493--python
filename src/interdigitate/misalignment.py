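"""Between-subject misalignment analysis.

Each subject's individually tailored regions (2 networks x 5 zones = 10
single vertices) define a 10x10 matrix of region-pair Fisher-z
correlations on that subject's replication data.  Applying subject i's
region vertices to subject j's data (meshes are registered by
construction, so vertex indices transfer directly) shows how the clean
two-network block structure breaks down under the spatial variability
between individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .connectivity import Z_SENTINEL, fisher_z
from .dissociation import RegionSet
from .simulate import SessionTimeseries, StudyDataset


@dataclass
class RegionMatrix:
    z: np.ndarray                     # (R, R) symmetric, diagonal sentinel
    labels: list[tuple[str, object]]  # (network, zone) per region
    data_subject: int
    region_subject: int

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


def region_matrix(sessions: list[SessionTimeseries], regions: RegionSet,
                  data_subject: int | None = None) -> RegionMatrix:
    """Session-averaged z matrix among a region set's vertices.

    ``sessions`` are the data subject's replication runs; ``regions``
    may come from any subject (that is the point of the analysis).
    """
    triples = regions.region_list()
    labels = [(net, zone) for net, zone, _ in triples]
    verts = np.array([v for _, _, v in triples], dtype=int)
    if len(sessions) == 0:
        raise ValueError("need at least one session")
    nv = sessions[0].n_vertices
    if verts.min() < 0 or verts.max() >= nv:
        raise IndexError("region vertex out of range for this mesh")
    acc = np.zeros((len(verts), len(verts)))
    for ts in sessions:
        x = ts.data[verts]
        r = np.clip(np.corrcoef(x), -1.0, 1.0)
        acc += fisher_z(r)
    z = acc / len(sessions)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, Z_SENTINEL)
    if data_subject is None:
        data_subject = sessions[0].subject_id
    return RegionMatrix(z=z, labels=labels, data_subject=int(data_subject),
                        region_subject=regions.subject_id)


def block_contrast(m: RegionMatrix) -> float:
    """Mean within-network off-diagonal z minus mean between-network z."""
    nets = np.array([net for net, _ in m.labels])
    same = nets[:, None] == nets[None, :]
    off = ~np.eye(m.n_regions, dtype=bool)
    within = m.z[same & off]
    between = m.z[~same]
    return float(within.mean() - between.mean())


def two_cluster_accuracy(m: RegionMatrix) -> float:
    """Accuracy of a spectral sign split against the network labels.

    Leading eigenvector of the (diagonal-zeroed, row-centered) z matrix;
    its sign pattern partitions the regions in two.  Returns the
    best-of-two-labelings accuracy, in [0.5, 1].
    """
    z0 = m.z.copy()
    np.fill_diagonal(z0, 0.0)
    z0 = z0 - z0.mean(axis=1, keepdims=True)
    z0 = (z0 + z0.T) / 2.0
    w, v = np.linalg.eigh(z0)
    split = v[:, np.argmax(np.abs(w))] >= 0
    truth = np.array([net == "A" for net, _ in m.labels])
    acc = np.mean(split == truth)
    return float(max(acc, 1.0 - acc))


def misalignment_battery(study: StudyDataset,
                         regions_by_subject: dict[int, RegionSet]) -> pd.DataFrame:
    """All region-source x data-subject matrices, summarized.

    For a 4-subject study this produces 16 matrices (4 own, 12 cross);
    the returned frame has one row per pair with the block contrast and
    the 2-cluster accuracy.
    """
    rows = []
    for region_subj, data_subj in product(sorted(regions_by_subject), study.subject_ids):
        m = region_matrix(study.replication(data_subj),
                          regions_by_subject[region_subj],
                          data_subject=data_subj)
        rows.append({
            "region_subject": region_subj,
            "data_subject": data_subj,
            "own": region_subj == data_subj,
            "block_contrast": block_contrast(m),
            "cluster_accuracy": two_cluster_accuracy(m),
        })
    return pd.DataFrame(rows)


def own_vs_cross(summary: pd.DataFrame) -> tuple[float, float]:
    """Mean block contrast for own-subject vs cross-subject matrices."""
    own = summary.loc[summary.own, "block_contrast"].mean()
    cross = summary.loc[~summary.own, "block_contrast"].mean()
    return float(own), float(cross)
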