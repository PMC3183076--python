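"""Simulator invariants: determinism, conservation, pathway fingerprints, MMR."""

import numpy as np
import pytest

from hdna.io import Genotypes
from hdna.simulate import (
    ConfigError,
    DegenerateMapError,
    SimConfig,
    apply_mmr,
    make_marker_map,
    simulate_meiosis,
)


def _pure(pathway: str, **kwargs) -> SimConfig:
    probs = {p: 0.0 for p in SimConfig().pathway_probs}
    probs[pathway] = 1.0
    cfg = SimConfig(pathway_probs=probs, **kwargs)
    return cfg.no_complications()


class TestConfig:
    def test_pathway_mix_must_sum_to_one(self):
        cfg = SimConfig()
        cfg.pathway_probs["simple_SDSA"] += 0.1
        with pytest.raises(ConfigError, match="sum to 1"):
            cfg.validate()

    def test_defaults_are_valid(self):
        SimConfig().validate()
        SimConfig.wild_type().validate()


class TestMarkerMap:
    def test_mean_spacing_within_ten_percent(self):
        """1 Mb chromosome at mean spacing 194 over 20 seeds."""
        spacings = []
        for seed in range(20):
            cfg = SimConfig(chromosome_sizes=[1_000_000])
            mm = make_marker_map(cfg, np.random.default_rng(seed))
            pos = mm.positions("chr01")
            spacings.append(np.diff(pos).mean())
        assert abs(np.mean(spacings) - 194) / 194 < 0.10

    def test_degenerate_spacing_rejected(self):
        cfg = SimConfig(chromosome_sizes=[1_000_000], marker_spacing=1_500_000)
        with pytest.raises(DegenerateMapError):
            make_marker_map(cfg, np.random.default_rng(0))

    def test_sparse_map_still_has_a_marker(self):
        cfg = SimConfig(chromosome_sizes=[1_000_000], marker_spacing=500_000)
        mm = make_marker_map(cfg, np.random.default_rng(0))
        assert len(mm.positions("chr01")) >= 1

    def test_same_seed_identical_maps(self):
        cfg = SimConfig(chromosome_sizes=[300_000, 200_000])
        a = make_marker_map(cfg, np.random.default_rng(9))
        b = make_marker_map(cfg, np.random.default_rng(9))
        assert a.table.equals(b.table)


class TestMeiosis:
    def test_deterministic_under_fixed_seed(self, small_sim_config):
        mm1, gt1, t1 = simulate_meiosis(small_sim_config, rng=42)
        mm2, gt2, t2 = simulate_meiosis(small_sim_config, rng=42)
        assert mm1.table.equals(mm2.table)
        assert np.array_equal(gt1.calls, gt2.calls)
        assert len(t1.events) == len(t2.events)

    def test_zero_dsbs_all_markers_mendelian(self):
        cfg = SimConfig(chromosome_sizes=[400_000] * 2, dsb_mean=0.0)
        mm, gt, truth = simulate_meiosis(cfg, rng=0)
        assert truth.events == []
        a = gt.calls.sum(axis=1)
        assert np.all(a == 4)

    def test_strand_conservation_sums_to_eight(self, small_sim_config):
        mm, gt, truth = simulate_meiosis(small_sim_config, rng=3)
        assert gt.calls.shape[1] == 8
        assert np.isin(gt.calls, [0, 1]).all()

    def test_pure_simple_sdsa_writes_one_strand_of_one_chromatid(self):
        for seed in range(50):
            cfg = _pure("simple_SDSA", chromosome_sizes=[400_000] * 2, dsb_mean=8.0)
            mm, gt, truth = simulate_meiosis(cfg, rng=seed)
            for ev in truth.events:
                assert ev.outcome == "NCO"
                written = [t for t in ev.tracts if not t.transient]
                assert len(written) == 1
                assert written[0].state == "hDNA"
                assert written[0].strand in (0, 1)

    def test_pure_resolution_co_records_reciprocal_exchange(self):
        for seed in range(50):
            cfg = _pure("dHJ_resolution_CO", chromosome_sizes=[400_000] * 2, dsb_mean=8.0)
            mm, gt, truth = simulate_meiosis(cfg, rng=seed)
            for ev in truth.events:
                assert ev.outcome == "CO"
                # broken and donor are non-sisters (different parents of origin)
                assert (ev.chromatid < 2) != (ev.donor < 2)

    def test_arm_balance_outside_tracts(self):
        """Away from written tracts and with no COs, every chromatid keeps
        its parent-of-origin haplotype."""
        cfg = _pure("simple_SDSA", chromosome_sizes=[400_000], dsb_mean=3.0)
        mm, gt, truth = simulate_meiosis(cfg, rng=5)
        in_tract = set()
        for ev in truth.events:
            for t in ev.tracts:
                in_tract.update(range(t.i0, t.i1))
        outside = np.array([k for k in range(len(mm)) if k not in in_tract])
        expected = np.repeat(np.array([1, 1, 0, 0], np.int8), 2)
        assert np.all(gt.calls[outside] == expected)


class TestMMR:
    def test_conversion_probability_one_gives_uniform_3_1(self):
        cfg = _pure("simple_SDSA", chromosome_sizes=[400_000], dsb_mean=6.0)
        cfg.mmr_mode = "wt"
        cfg.p_conv = 1.0
        mm, gt, truth = simulate_meiosis(cfg, rng=1)
        assert gt.mode == "tetrad"
        ratios = gt.calls.sum(axis=1)
        assert set(np.unique(ratios)) <= {1, 2, 3}
        # at least one conversion tract present
        assert np.any(ratios != 2)

    def test_conversion_probability_zero_erases_all_events(self):
        cfg = _pure("simple_SDSA", chromosome_sizes=[400_000], dsb_mean=6.0)
        cfg.mmr_mode = "wt"
        cfg.p_conv = 0.0
        mm, gt, truth = simulate_meiosis(cfg, rng=1)
        assert np.all(gt.calls.sum(axis=1) == 2)

    def test_converted_fraction_matches_binomial(self):
        """Over ~1000 tracts at p_conv = 0.5, the converted fraction is
        within three standard errors of 0.5."""
        n_conv = n_tot = 0
        for seed in range(15):
            cfg = _pure("simple_SDSA", chromosome_sizes=[600_000] * 4, dsb_mean=35.0)
            cfg.mmr_mode = "wt"
            cfg.p_conv = 0.5
            mm, gt, truth = simulate_meiosis(cfg, rng=seed)
            for _, decision in truth.mmr_actions:
                n_tot += 1
                n_conv += decision == "convert"
        assert n_tot > 800
        se = 0.5 / np.sqrt(n_tot)
        assert abs(n_conv / n_tot - 0.5) < 3 * se

    def test_msh2_mode_rejected(self):
        with pytest.raises(ConfigError, match="wild-type"):
            apply_mmr({}, None, 0.5, np.random.default_rng(0), mmr_mode="msh2")
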