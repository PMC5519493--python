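"""Replication-scale synthetic experiments.

High-level flows that run the full method on generated studies: the
powered dissociation battery, null-calibration batteries, misalignment
replicates and parcellation recovery.  These are the canonical
experiment entry points used by the examples, the test suite and the
results-reproduction script; every flow is a pure function of its seed.

Problem sizes are desk-scale by design: subdivision level 3 or 4
(642/2,562 vertices per hemisphere) instead of the full-resolution
level-6 template, with the study design (subjects, session counts,
frames, split) kept at the published structure.
"""

from __future__ import annotations

import numpy as np

from .connectivity import mean_z_matrix, mean_z_row_view
from .dissociation import (
    DissociationReport,
    RegionSet,
    anova_2x2,
    extract_cell_values,
    select_regions,
)
from .mesh import SurfaceMesh, build_icosphere
from .misalignment import misalignment_battery, own_vs_cross
from .parcellation import kmeans_parcellate, match_and_score
from .preprocess import PreprocParams, preprocess_session, preprocess_study
from .seed_search import SeedCriteria, find_seed_pair
from .simulate import (
    GeneratorParams,
    session_seed,
    simulate_session,
    simulate_study,
    subject_template,
)


def derive_seed(base_seed: int, *key: int) -> int:
    """Deterministic sub-seed (< 2**31) from a base seed and a key path."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


def dissociated_battery(
    params: GeneratorParams,
    preproc: PreprocParams | None = None,
    criteria: SeedCriteria | None = None,
    search_zone: int = 0,
    alpha: float = 0.01,
    return_regions: bool = False,
):
    """Full per-subject pipeline: simulate, preprocess, find seeds on the
    discovery half, select a priori regions, run the 2x2 battery on the
    replication half.

    Streams one subject at a time and computes only the seed rows of the
    discovery connectivity matrix, so it scales to level-4 meshes in
    minutes on one CPU.
    """
    preproc = preproc or PreprocParams()
    criteria = criteria or SeedCriteria()
    mesh = build_icosphere(params.subdivision_level)
    test_zones = [z for z in range(params.n_zones) if z != search_zone]
    results = []
    regions_by_subject: dict[int, RegionSet] = {}
    seed_truth: dict[int, tuple[int, int]] = {}
    for s in range(params.n_subjects):
        tpl = subject_template(mesh, params, s)
        disc, repl = [], []
        for r in range(1, params.n_sessions + 1):
            ts = simulate_session(tpl, params, seed=session_seed(params, s, r),
                                  run_id=r, subject_id=s)
            ts = preprocess_session(ts, mesh, preproc)
            (disc if r % 2 == 1 else repl).append(ts)
        zone_rows = np.flatnonzero(tpl.zone_label == search_zone)
        zview = mean_z_row_view(disc, zone_rows, "discovery")
        sa, sb, *_ = find_seed_pair(zview, search_zone, tpl.zone_label,
                                    criteria, mesh=mesh)
        seed_truth[s] = (int(tpl.assignment[sa]), int(tpl.assignment[sb]))
        regs = select_regions(zview, sa, sb, tpl.zone_label, test_zones,
                              subject_id=s)
        regions_by_subject[s] = regs
        table = extract_cell_values(repl, regs)
        for zone in regs.zone_targets:
            sub = table[table.zone == zone]
            cells = np.stack([
                [sub[(sub.seed_net == sn) & (sub.target_net == tn)]
                 .sort_values("session")["z"].to_numpy() for tn in "AB"]
                for sn in "AB"])
            res = anova_2x2(cells)
            res.zone = zone
            res.subject_id = s
            results.append(res)
    n_sig = sum(r.p_interaction < alpha for r in results)
    n_cross = sum(r.crossover_class == "crossover" for r in results)
    report = DissociationReport(results=results, alpha=alpha,
                                n_significant=n_sig, n_crossover=n_cross,
                                null_expectation=alpha * len(results))
    if return_regions:
        return report, regions_by_subject, seed_truth
    return report


def power_battery(master_seed: int, level: int = 3) -> DissociationReport:
    """The powered double-dissociation battery at its stated conditions.

    Two interdigitated networks, loading 1.0, vertex noise sd 1.0,
    4 subjects with 12 discovery + 12 replication sessions of 300 frames
    at TR = 1 s; one search zone plus five distributed test zones, so
    the battery comprises 4 x 5 = 20 two-way ANOVAs with 12 values per
    cell.
    """
    params = GeneratorParams(subdivision_level=level, n_subjects=4,
                             n_sessions=24, frames_per_run=300,
                             network_loading=1.0, vertex_noise_sd=1.0,
                             master_seed=master_seed)
    return dissociated_battery(params)


def spread_vertices(mesh: SurfaceMesh, n: int) -> list[int]:
    """n mutually distant vertices by farthest-point sampling from 0."""
    chosen = [0]
    dmin = mesh.hop_distance(0)
    for _ in range(n - 1):
        nxt = int(np.argmax(np.where(np.isinf(dmin), float(mesh.n_vertices), dmin)))
        chosen.append(nxt)
        dmin = np.minimum(dmin, mesh.hop_distance(nxt))
    return chosen


def null_battery_pvalues(n_studies: int, base_seed: int, level: int = 2,
                         frames: int = 128) -> np.ndarray:
    """Interaction p-values from batteries on null studies.

    Studies with network loading 0 (no planted structure) and
    arbitrarily placed (well-separated) region vertices; each study
    contributes 4 subjects x 5 zones = 20 p-values, computed on the
    standard preprocessed replication sessions.  Under the null these
    should be uniform.
    """
    mesh = build_icosphere(level)
    chosen = spread_vertices(mesh, 12)
    regs = RegionSet(subject_id=0, seed_a=chosen[0], seed_b=chosen[1],
                     zone_targets={z: (chosen[2 + 2 * z], chosen[3 + 2 * z])
                                   for z in range(5)})
    pp = PreprocParams(n_discard=4)
    pvals = []
    for study_i in range(n_studies):
        params = GeneratorParams(
            subdivision_level=level, n_subjects=4, n_sessions=24,
            frames_per_run=frames, network_loading=0.0,
            n_zones=2, parcel_radius=1, zone_radius=1, jitter_steps=0,
            master_seed=derive_seed(base_seed, 0xA11, study_i))
        tpl = subject_template(mesh, params, 0)
        for s in range(params.n_subjects):
            repl = [preprocess_session(
                simulate_session(tpl, params,
                                 seed=session_seed(params, s, r),
                                 run_id=r, subject_id=s), mesh, pp)
                for r in range(2, params.n_sessions + 1, 2)]
            table = extract_cell_values(repl, regs)
            for zone in regs.zone_targets:
                sub = table[table.zone == zone]
                cells = np.stack([
                    [sub[(sub.seed_net == sn) & (sub.target_net == tn)]
                     .sort_values("session")["z"].to_numpy() for tn in "AB"]
                    for sn in "AB"])
                pvals.append(anova_2x2(cells).p_interaction)
    return np.asarray(pvals)


def misalignment_replicate(master_seed: int, level: int = 3,
                           n_sessions: int = 12, frames: int = 200
                           ) -> tuple[float, float]:
    """One 4-subject study's (own, cross) mean block contrasts.

    Per-subject spatial jitter equals the parcel radius, the regime in
    which between-subject transfer of region vertices should destroy
    the two-network block structure.
    """
    params = GeneratorParams(subdivision_level=level, n_subjects=4,
                             n_sessions=n_sessions, frames_per_run=frames,
                             jitter_steps=2, parcel_radius=2,
                             master_seed=master_seed)
    study = simulate_study(params)
    spp = preprocess_study(study)
    regions = {}
    for s in spp.subject_ids:
        tpl = study.templates[s]
        zd = mean_z_matrix(spp.discovery(s), "discovery")
        sa, sb, *_ = find_seed_pair(zd, 0, tpl.zone_label, SeedCriteria(),
                                    mesh=study.mesh)
        regions[s] = select_regions(zd, sa, sb, tpl.zone_label,
                                    [1, 2, 3, 4, 5], subject_id=s)
    return own_vs_cross(misalignment_battery(spp, regions))


def parcellation_recovery(loading: float, master_seed: int, level: int = 3,
                          k: int = 3, n_sessions: int = 24,
                          frames: int = 300) -> float:
    """ARI of k-means labels vs the planted template at one loading.

    One subject's discovery half (odd sessions), preprocessed, clustered
    with k matched to the planted structure plus background.
    """
    params = GeneratorParams(subdivision_level=level, n_subjects=1,
                             n_sessions=n_sessions, frames_per_run=frames,
                             network_loading=loading, master_seed=master_seed)
    study = simulate_study(params, subjects=[0])
    spp = preprocess_study(study)
    res = kmeans_parcellate(spp.discovery(0), k=k, n_restarts=10,
                            seed=derive_seed(master_seed, 0x12))
    res = match_and_score(res, study.templates[0])
    return float(res.ari)
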