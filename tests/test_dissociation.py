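import numpy as np
import pandas as pd
import pytest
import scipy.stats

from interdigitate import (
    GeneratorParams,
    RegionSet,
    anova_2x2,
    classify_crossover,
    extract_cell_values,
    preprocess_study,
    run_battery,
    select_regions,
    simulate_study,
)
from interdigitate.connectivity import Z_SENTINEL, mean_z_matrix
from interdigitate.dissociation import ProvenanceError
from interdigitate.experiments import null_battery_pvalues
from tests.conftest import make_ts


def statsmodels_anova(cells):
    """Independent two-way ANOVA oracle via an OLS fit."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = []
    for i, a in enumerate("AB"):
        for j, b in enumerate("AB"):
            for v in cells[i, j]:
                rows.append({"seed": a, "target": b, "z": v})
    df = pd.DataFrame(rows)
    fit = ols("z ~ C(seed) * C(target)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    inter = tab.loc["C(seed):C(target)"]
    return float(inter["F"]), float(inter["PR(>F)"])


class TestAnova:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_oracle(self, seed):
        cells = np.random.default_rng(seed).normal(size=(2, 2, 12))
        res = anova_2x2(cells)
        f_ref, p_ref = statsmodels_anova(cells)
        assert res.F_interaction == pytest.approx(f_ref, abs=1e-8)
        assert res.p_interaction == pytest.approx(p_ref, abs=1e-8)

    def test_constant_cells(self):
        res = anova_2x2(np.full((2, 2, 5), 3.0))
        assert res.F_interaction == 0.0 and res.p_interaction == 1.0

    def test_error_df(self):
        res = anova_2x2(np.random.default_rng(1).normal(size=(2, 2, 12)))
        assert res.df == (1, 44)

    def test_shift_invariance(self):
        cells = np.random.default_rng(2).normal(size=(2, 2, 8))
        a = anova_2x2(cells)
        b = anova_2x2(cells + 7.3)
        assert a.F_interaction == pytest.approx(b.F_interaction, rel=1e-9)

    def test_factor_swap_equivariance(self):
        cells = np.random.default_rng(3).normal(size=(2, 2, 8))
        a = anova_2x2(cells)
        b = anova_2x2(np.transpose(cells, (1, 0, 2)))
        assert a.F_interaction == pytest.approx(b.F_interaction, rel=1e-12)
        assert a.F_seed == pytest.approx(b.F_target, rel=1e-12)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            anova_2x2(np.zeros((2, 3, 4)))
        with pytest.raises(ValueError):
            anova_2x2(np.zeros((2, 2, 1)))


class TestCrossover:
    def test_clean_crossover(self):
        assert classify_crossover([[0.6, 0.1], [0.1, 0.6]]) == "crossover"

    def test_ordinal_interaction(self):
        # positive contrast but B's preference inverted: 0.5 > 0.55 fails
        assert classify_crossover([[0.6, 0.4], [0.55, 0.5]]) == "ordinal"

    def test_flat_means(self):
        assert classify_crossover([[0.3, 0.3], [0.3, 0.3]]) == "none"


@pytest.fixture(scope="module")
def mini_study():
    """4 subjects, 4 runs x 128 frames at level 3."""
    p = GeneratorParams(subdivision_level=3, n_subjects=4, n_sessions=4,
                        frames_per_run=128, master_seed=21)
    study = simulate_study(p)
    return study, preprocess_study(study)


@pytest.fixture(scope="module")
def mini_regions(mini_study):
    study, spp = mini_study
    regions = {}
    for s in study.subject_ids:
        tpl = study.templates[s]
        zd = mean_z_matrix(spp.discovery(s), "discovery")
        seeds = (int(tpl.anchors[0][1]), int(tpl.anchors[0][2]))
        regions[s] = select_regions(zd, *seeds, tpl.zone_label,
                                    [1, 2, 3, 4, 5], subject_id=s)
    return regions


class TestExtractAndBattery:
    def test_one_value_per_session_and_cell(self, mini_study, mini_regions):
        study, spp = mini_study
        table = extract_cell_values(spp.replication(0), mini_regions[0])
        counts = table.groupby(["zone", "seed_net", "target_net"]).size()
        assert (counts == len(spp.replication(0))).all()

    def test_replication_firewall(self, mini_study, mini_regions):
        study, spp = mini_study
        with pytest.raises(ProvenanceError):
            extract_cell_values(spp.discovery(0), mini_regions[0])
        bad = RegionSet(subject_id=0, seed_a=0, seed_b=1,
                        zone_targets={1: (10, 20)}, provenance="replication")
        with pytest.raises(ProvenanceError):
            extract_cell_values(spp.replication(0), bad)

    def test_region_selection_requires_discovery_matrix(self, mini_study):
        study, spp = mini_study
        zr = mean_z_matrix(spp.replication(0), "replication")
        with pytest.raises(ProvenanceError):
            select_regions(zr, 0, 1, study.templates[0].zone_label, [1, 2])

    def test_distinct_vertices_enforced(self):
        with pytest.raises(ValueError):
            RegionSet(subject_id=0, seed_a=3, seed_b=3, zone_targets={})

    def test_battery_structure(self, mini_study, mini_regions):
        study, spp = mini_study
        report = run_battery(spp, mini_regions, alpha=0.01)
        assert report.n_tests == 20  # 4 subjects x 5 zones
        assert all(r.n_per_cell == 2 for r in report.results)
        assert report.null_expectation == pytest.approx(0.2)
        df = report.to_frame()
        assert len(df) == 20 and df.p_interaction.between(0, 1).all()

    def test_missing_subject_regions(self, mini_study, mini_regions):
        study, spp = mini_study
        partial = {0: mini_regions[0]}
        with pytest.raises(ValueError, match="missing region set"):
            run_battery(spp, partial)


def test_noise_free_cells_hit_closed_form(template3):
    """Without noise, same-network seed-target z is exactly the r = 1
    sentinel and cross-network values are near zero."""
    p = GeneratorParams(subdivision_level=3, n_subjects=1, n_sessions=4,
                        frames_per_run=128, vertex_noise_sd=0.0,
                        global_signal_sd=0.0, jitter_steps=0, master_seed=2)
    study = simulate_study(p)
    tpl = study.templates[0]
    regions = RegionSet(
        subject_id=0,
        seed_a=int(tpl.anchors[0][1]), seed_b=int(tpl.anchors[0][2]),
        zone_targets={z: (int(tpl.anchors[z][1]), int(tpl.anchors[z][2]))
                      for z in (1, 2)})
    table = extract_cell_values(study.replication(0), regions)
    same = table[table.seed_net == table.target_net]
    cross = table[table.seed_net != table.target_net]
    assert np.allclose(same.z, Z_SENTINEL)
    # cross-network latents are independent; finite-length sample
    # correlations stay far below the within-network sentinel
    assert np.max(np.abs(cross.z)) < 1.0


def test_null_interaction_pvalues_uniform():
    """Type-I calibration: p-values from null batteries are uniform."""
    pvals = null_battery_pvalues(n_studies=25, base_seed=77)
    assert len(pvals) == 500
    ks = scipy.stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
    assert np.mean(pvals < 0.01) * 20 <= 1.0
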