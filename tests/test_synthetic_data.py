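import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coopnet.formats_io import read_bed, read_fasta
from coopnet.motif_scan import best_hit, max_score
from coopnet.peak_annotation import assign_peaks
from coopnet.synthetic_data import (
    CRE,
    PARTNER_LIBRARY,
    PlantedPartner,
    ScenarioConfig,
    TRE,
    generate_scenario,
    make_peak_sequences,
    make_tss_and_binding,
    ode_response,
    simulate_coop_dataset,
    simulate_expression,
    tf_pulse,
)


class TestPeakSequences:
    def test_fraction_one_plants_every_sequence(self):
        cfg = ScenarioConfig(seed=1, n_peaks=30, planted_partners=[
            PlantedPartner(PARTNER_LIBRARY["PTN2"], gap=10, fraction=1.0)])
        seqs, truth = make_peak_sequences(cfg)
        planted = truth[truth["element"] == "PTN2"]
        assert len(planted) == 30
        # planted site scores at the PWM maximum in every sequence
        pwm = PARTNER_LIBRARY["PTN2"]
        for seq in seqs.values():
            assert best_hit(seq, pwm).score == pytest.approx(max_score(pwm))

    def test_same_seed_reproducible(self):
        cfg = ScenarioConfig(seed=9, n_peaks=20, planted_partners=[
            PlantedPartner(PARTNER_LIBRARY["PTN1"], gap=5)])
        s1, t1 = make_peak_sequences(cfg)
        s2, t2 = make_peak_sequences(cfg)
        assert s1 == s2
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_count_within_binomial_interval(self):
        n, frac = 500, 0.6
        cfg = ScenarioConfig(seed=3, n_peaks=n, planted_partners=[
            PlantedPartner(PARTNER_LIBRARY["PTN3"], gap=8, fraction=frac)])
        _, truth = make_peak_sequences(cfg)
        count = (truth["element"] == "PTN3").sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], n, frac)
        assert lo <= count <= hi

    def test_every_sequence_has_a_primary(self):
        cfg = ScenarioConfig(seed=2, n_peaks=25)
        seqs, truth = make_peak_sequences(cfg)
        assert (truth["element"] == "TRE").sum() == 25

    def test_incompatible_gap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            make_peak_sequences(ScenarioConfig(n_peaks=2, planted_partners=[
                PlantedPartner(PARTNER_LIBRARY["PTN1"], gap=45)]))

    def test_cre_primary_supported(self):
        cfg = ScenarioConfig(seed=4, n_peaks=5, primary_motif="CRE")
        seqs, _ = make_peak_sequences(cfg)
        for seq in seqs.values():
            assert best_hit(seq, CRE).score == pytest.approx(max_score(CRE))


class TestOdeResponse:
    def test_steady_state_without_force_is_constant(self):
        t = np.linspace(0, 8, 9)
        out = ode_response(t, B=2.0, S=0.0, D=0.5, x0=4.0)
        np.testing.assert_allclose(out, 4.0, atol=1e-12)

    def test_fast_decay_quasi_steady_state(self):
        # for large D the response tracks B/D + S f(t)/D
        t = np.array([1.0, 2.0, 4.0, 6.0])
        D = 40.0
        grid = np.linspace(0, 8, 4001)
        out = ode_response(t, B=4.0, S=3.0, D=D, x0=4.0 / D, grid=grid)
        expected = 4.0 / D + 3.0 * tf_pulse(t) / D
        np.testing.assert_allclose(out, expected, rtol=0.05)

    def test_non_positive_decay_rejected(self):
        with pytest.raises(ValueError, match="decay"):
            ode_response([1.0], 1.0, 1.0, 0.0, 1.0)


class TestSimulateExpression:
    def test_design_shape_and_metadata(self):
        cfg = ScenarioConfig(seed=5, n_genes=20, n_targets=5)
        expr, truth = simulate_expression(cfg)
        assert expr.data.shape == (21, 32)  # TF gene + 20, 2 cond x 4 t x 4 reps
        assert expr.conditions == ["WKY", "congenic"]
        assert expr.times == [0.0, 2.0, 4.0, 8.0]
        assert (truth["kind"] == "target").sum() == 5

    def test_same_seed_identical_matrix(self):
        cfg = ScenarioConfig(seed=8, n_genes=15, n_targets=4)
        e1, _ = simulate_expression(cfg)
        e2, _ = simulate_expression(cfg)
        pd.testing.assert_frame_equal(e1.data, e2.data)

    def test_attenuated_condition_suppresses_response(self):
        cfg = ScenarioConfig(seed=6, n_genes=30, n_targets=10, noise_sd=0.05)
        expr, truth = simulate_expression(cfg)
        targets = truth.loc[truth["kind"] == "target", "gene_id"]
        wky = expr.select(condition="WKY")
        cong = expr.select(condition="congenic")

        def response(sub, g):
            v = sub.data.loc[g]
            t = sub.samples["time_h"]
            return v[t == 2.0].mean() - v[t == 0.0].mean()

        resp_wky = np.array([response(wky, g) for g in targets])
        resp_cong = np.array([response(cong, g) for g in targets])
        assert resp_wky.mean() > 5 * abs(resp_cong.mean())

    def test_coop_blocks_elevate_within_block_correlation(self):
        cfg = ScenarioConfig(seed=7, n_genes=60, n_targets=0,
                             coop_block_sizes=(10,), coop_block_corr=0.7)
        expr, truth = simulate_expression(cfg)
        block = truth.loc[truth["kind"] == "coop_block", "gene_id"].tolist()
        others = truth.loc[truth["kind"] == "background", "gene_id"].tolist()[:10]
        sub = expr.select(condition="WKY")
        rb = np.corrcoef(sub.data.loc[block].to_numpy())
        ro = np.corrcoef(sub.data.loc[others].to_numpy())
        off = ~np.eye(10, dtype=bool)
        assert rb[off].mean() > 0.4 > ro[off].mean()


class TestCoopDataset:
    def test_within_class_correlations_near_nominal(self):
        binding, expr = simulate_coop_dataset(n_both=40, n_a_only=40, n_b_only=40,
                                              n_samples=200, r_both=0.7, r_single=0.1,
                                              seed=11)
        both = sorted(binding.bound_genes("TF_A") & binding.bound_genes("TF_B"))
        vals = expr.data.loc[both].to_numpy()
        r = np.corrcoef(vals)
        off = ~np.eye(len(both), dtype=bool)
        assert r[off].mean() == pytest.approx(0.7, abs=0.1)


class TestTssAndBinding:
    def test_promoter_peaks_marked_in_truth_binding(self):
        cfg = ScenarioConfig(seed=2, n_genes=50, n_targets=10, n_peaks=60)
        mapping = {f"g{i:04d}": "PTN1" for i in range(10)}
        tss, peaks, binding, truth = make_tss_and_binding(cfg, mapping)
        for g in mapping:
            assert binding.indicator.loc[g, "PTN1"] == 1

    def test_boundary_peak_excluded_from_window(self):
        cfg = ScenarioConfig(seed=2, n_genes=50, n_targets=0, n_peaks=30)
        tss, peaks, _, truth = make_tss_and_binding(cfg, {})
        assigned = assign_peaks([p for p in peaks if p.posterior > 0.9], tss)
        by_name = {a.peak.name: a for a in assigned}
        edge = truth.loc[truth["role"] == "window-edge", "peak"].iloc[0]
        outside = truth.loc[truth["role"] == "outside-window", "peak"].iloc[0]
        assert edge in by_name and by_name[edge].distance == 20_000
        assert outside not in by_name

    def test_same_seed_identical_peaks(self):
        cfg = ScenarioConfig(seed=3, n_genes=40, n_targets=5, n_peaks=30)
        mapping = {f"g{i:04d}": "PTN2" for i in range(5)}
        _, p1, _, _ = make_tss_and_binding(cfg, mapping)
        _, p2, _, _ = make_tss_and_binding(cfg, mapping)
        assert p1 == p2


class TestGenerateScenario:
    def test_written_files_are_consistent(self, tmp_path):
        cfg = ScenarioConfig(seed=5, n_genes=40, n_targets=10, n_peaks=40,
                             planted_partners=[PlantedPartner(PARTNER_LIBRARY["PTN1"], gap=10)])
        paths = generate_scenario(cfg, tmp_path / "scen")
        peaks = read_bed(paths["peaks_bed"])
        seqs = read_fasta(paths["peaks_fasta"])
        assert {p.name for p in peaks} == set(seqs)
        truth_sets = open(paths["truth_sets"]).read().splitlines()
        assert len(truth_sets) == 1  # one partner -> one planted set
        members = truth_sets[0].split("\t")[2:]
        assert len(members) == 10
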