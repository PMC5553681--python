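"""Within/between-chip cutoffs and the four-stage cascade."""

import numpy as np
import pandas as pd
import pytest

from mscmir import normalization as nm
from mscmir import synthetic_data as sd
from mscmir import variability_filters as vf


def _sheet(entries):
    return pd.DataFrame(
        [(a, d, p, i + 1, "MSC_set1") for i, (a, d, p) in enumerate(entries)],
        columns=["array_id", "donor_id", "passage_label", "tech_rep_index",
                 "cohort"],
    )


class TestWithinChip:
    def test_zero_noise_all_zero(self, zero_noise_sim):
        _, (probes, _, _) = zero_noise_sim
        cutoffs = vf.within_chip_cutoffs(probes)
        np.testing.assert_allclose(cutoffs.to_numpy(), 0.0, atol=1e-10)

    def test_hand_example_median_of_two_sds(self):
        """Probes {1,3} and {2,2} on log2 scale: SDs {sqrt2, 0} -> 0.7071."""
        rows = []
        for arr, vals in (("a1", [1.0, 3.0]), ("a2", [2.0, 2.0])):
            for j, v in enumerate(vals):
                rows.append([arr, f"p{j}", "s1", "m1", "experimental",
                             "miRNA", 2.0 ** v])
        probes = pd.DataFrame(rows, columns=["array_id", "probe_id",
                                             "sequence_id", "mirna_name",
                                             "control_type", "rna_class",
                                             "raw_signal"])
        # identical column multisets {2,8} vs {4,4}? use afe-free path: the
        # quantile step maps each array's values onto shared order statistics,
        # so compute the expected SDs from the normalized values directly
        cutoffs = vf.within_chip_cutoffs(probes)
        pm = nm.quantile_normalize(nm.probe_matrix(probes))
        sds = [pm["a1"].std(ddof=1), pm["a2"].std(ddof=1)]
        assert cutoffs["s1"] == pytest.approx(float(np.median(sds)))

    def test_hand_example_without_normalization_distortion(self):
        """Same layout, arrays already rank-identical: cutoff = (sqrt2+0)/2."""
        rows = []
        for arr, vals in (("a1", [1.0, 3.0]), ("a2", [2.0, 2.0])):
            for j, v in enumerate(vals):
                rows.append([arr, f"p{j}", "s1", "m1", "experimental",
                             "miRNA", 2.0 ** v])
        probes = pd.DataFrame(rows, columns=["array_id", "probe_id",
                                             "sequence_id", "mirna_name",
                                             "control_type", "rna_class",
                                             "raw_signal"])
        pm = nm.probe_matrix(probes)
        log2 = np.log2(pm)
        seq_map = pd.Series("s1", index=pm.index)
        sd_per_array = log2.groupby(seq_map).std(ddof=1)
        # median of two values is their mean: (sqrt(2) + 0) / 2
        assert float(sd_per_array.median(axis=1).iloc[0]) == pytest.approx(
            (np.sqrt(2) + 0) / 2)

    def test_singleton_probe_cutoff_zero_with_warning(self):
        rows = [["a1", "p1", "s1", "m1", "experimental", "miRNA", 8.0],
                ["a2", "p1", "s1", "m1", "experimental", "miRNA", 8.0],
                ["a1", "q1", "s2", "m2", "experimental", "miRNA", 4.0],
                ["a1", "q2", "s2", "m2", "experimental", "miRNA", 6.0],
                ["a2", "q1", "s2", "m2", "experimental", "miRNA", 4.0],
                ["a2", "q2", "s2", "m2", "experimental", "miRNA", 6.0]]
        probes = pd.DataFrame(rows, columns=["array_id", "probe_id",
                                             "sequence_id", "mirna_name",
                                             "control_type", "rna_class",
                                             "raw_signal"])
        with pytest.warns(UserWarning, match="single probe"):
            cutoffs = vf.within_chip_cutoffs(probes)
        assert cutoffs["s1"] == 0.0
        assert cutoffs["s2"] > 0.0

    def test_monte_carlo_sigma_probe_concentration(self):
        """With sigma_probe=0.1 the cutoffs concentrate near 0.1."""
        cfg = sd.SimulationConfig(
            n_donors=4, n_sequences=60, n_mirnas=30, n_duplicate_pairs=0,
            n_negative_controls=40, n_rrna_trna=0, expressed_fraction=0.5,
            sigma_probe=0.1, sigma_array=0.0, sigma_donor=0.0,
            sigma_seq_array=0.0, seed=21,
        )
        probes, _, _ = sd.simulate_experiment(cfg)
        cutoffs = vf.within_chip_cutoffs(probes)
        # sample SD underestimates sigma slightly (c4 bias) at n=4..8
        assert abs(cutoffs.median() - 0.1) < 0.02


class TestBetweenChip:
    def test_identical_replicates_zero(self, zero_noise_sim):
        _, (probes, sheet, _) = zero_noise_sim
        expr, _ = nm.prepare_matrices(probes)
        cutoffs = vf.between_chip_cutoffs(expr, sheet)
        np.testing.assert_allclose(cutoffs.to_numpy(), 0.0, atol=1e-9)

    def test_constant_groups_sd_one(self):
        sheet = _sheet([("a1", "d1", "P3"), ("a2", "d1", "P3"),
                        ("a3", "d1", "P3"), ("b1", "d1", "P7"),
                        ("b2", "d1", "P7"), ("b3", "d1", "P7")])
        mat = pd.DataFrame([[5.0, 6.0, 7.0, 5.0, 6.0, 7.0]], index=["s1"],
                           columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        cutoffs = vf.between_chip_cutoffs(mat, sheet)
        assert cutoffs["s1"] == pytest.approx(1.0)

    def test_no_replicated_group_raises(self):
        sheet = _sheet([("a1", "d1", "P3"), ("b1", "d2", "P3")])
        mat = pd.DataFrame([[5.0, 6.0]], index=["s1"], columns=["a1", "b1"])
        with pytest.raises(ValueError, match="technical replicates"):
            vf.between_chip_cutoffs(mat, sheet)

    def test_monte_carlo_sigma_array_on_unnormalized_scale(self):
        """Pure array offsets of SD 0.2 appear as ~0.2 between-chip SD.

        Measured on the unnormalized collapsed log2 matrix; quantile
        normalization removes shared array offsets by construction.
        """
        cfg = sd.SimulationConfig(
            n_donors=4, n_sequences=50, n_mirnas=25, n_duplicate_pairs=0,
            n_negative_controls=20, n_rrna_trna=0, expressed_fraction=0.5,
            sigma_probe=0.0, sigma_array=0.2, sigma_donor=0.0,
            sigma_seq_array=0.0, seed=2,
        )
        probes, sheet, _ = sd.simulate_experiment(cfg)
        raw = np.log2(nm.collapse_probe_replicates(probes))
        cutoffs = vf.between_chip_cutoffs(raw, sheet)
        assert abs(cutoffs.median() - 0.2) < 0.08


class TestCascade:
    def _run(self, probes, sheet, magnitude_cutoff=5.4, **kw):
        expr, _ = nm.prepare_matrices(probes)
        within = vf.within_chip_cutoffs(probes)
        between = vf.between_chip_cutoffs(expr, sheet)
        trace = vf.apply_cascade(expr, sheet, within, between,
                                 magnitude_cutoff=magnitude_cutoff, **kw)
        return expr, trace

    def test_zero_difference_fails_stage_one(self, zero_noise_sim):
        _, (probes, sheet, _) = zero_noise_sim
        _, trace = self._run(probes, sheet)
        assert not trace["pass_within"].astype(bool).any()
        # later stages were never evaluated
        assert trace["pass_between"].isna().all()
        assert trace["final_eligible"].sum() == 0

    def test_generative_oracle_spiked_survive_null_fail(self):
        """Spiked sequences pass all four stages; nulls fail stage 1 or 3.

        Run on the collapsed log2 matrix without cross-array normalization
        (sigma_array = 0) so the check isolates the cascade's selection
        logic from normalization effects.
        """
        effects = {f"seq{i:04d}": {"P7": 0.5 if i % 2 else -0.5}
                   for i in range(8)}
        cfg = sd.SimulationConfig(
            n_donors=6, n_sequences=80, n_mirnas=40, n_duplicate_pairs=0,
            n_negative_controls=60, n_rrna_trna=0, expressed_fraction=0.5,
            sigma_probe=0.05, sigma_seq_array=0.03, sigma_donor=0.2,
            sigma_array=0.0, sigma_vs_intensity_slope=0.0,
            passage_effects=effects, seed=13,
        )
        probes, sheet, truth = sd.simulate_experiment(cfg)
        matrix = np.log2(nm.collapse_probe_replicates(probes))
        within = vf.within_chip_cutoffs(probes)
        between = vf.between_chip_cutoffs(matrix, sheet)
        trace = vf.apply_cascade(matrix, sheet, within, between,
                                 magnitude_cutoff=5.4)
        eligible = set(trace.index[trace["final_eligible"]])
        assert eligible == set(effects)

    def test_stage_four_independent_failure(self):
        """A below-background sequence passing stages 1-3 fails magnitude."""
        sheet = _sheet([(f"a{d}{p}{r}", f"d{d}", p)
                        for d in (1, 2, 3) for p in ("P3", "P7")
                        for r in (1, 2)])
        rng = np.random.default_rng(0)
        vals = {}
        for col in sheet["array_id"]:
            p = sheet.set_index("array_id").loc[col, "passage_label"]
            vals[col] = 4.0 + (1.0 if p == "P7" else 0.0) + rng.normal(0, 0.01)
        mat = pd.DataFrame(vals, index=["s1"])
        within = pd.Series(0.05, index=["s1"])
        between = pd.Series(0.05, index=["s1"])
        trace = vf.apply_cascade(mat, sheet, within, between,
                                 magnitude_cutoff=5.4)
        row = trace.loc["s1"]
        assert bool(row["pass_within"]) and bool(row["pass_between"])
        assert bool(row["pass_biological"])
        assert row["pass_magnitude"] is False or not bool(row["pass_magnitude"])
        assert not row["final_eligible"]

    def test_conservation_counts(self, small_sim):
        probes, sheet, _ = small_sim
        _, trace = self._run(probes, sheet)
        counts = vf.cascade_counts(trace)
        assert counts["total"] == len(trace)
        assert (counts["eliminated_within"] + counts["eliminated_between"]
                + counts["eliminated_biological"]
                + counts["eliminated_magnitude"] + counts["eligible"]
                ) == counts["total"]
        assert counts["eligible"] == int(trace["final_eligible"].sum())

    def test_order_invariance(self, small_sim):
        probes, sheet, _ = small_sim
        expr, _ = nm.prepare_matrices(probes)
        within = vf.within_chip_cutoffs(probes)
        between = vf.between_chip_cutoffs(expr, sheet)
        t1 = vf.apply_cascade(expr, sheet, within, between, 5.4)
        perm = expr.sample(frac=1.0, random_state=1)
        t2 = vf.apply_cascade(perm, sheet, within, between, 5.4)
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())

    def test_tightening_cutoffs_shrinks_eligible(self, small_sim):
        probes, sheet, _ = small_sim
        expr, _ = nm.prepare_matrices(probes)
        within = vf.within_chip_cutoffs(probes)
        between = vf.between_chip_cutoffs(expr, sheet)
        base = vf.apply_cascade(expr, sheet, within, between, 5.4, alpha=0.05)
        tighter = vf.apply_cascade(expr, sheet, within * 2, between * 2,
                                   5.8, alpha=0.01)
        e1 = set(base.index[base["final_eligible"]])
        e2 = set(tighter.index[tighter["final_eligible"]])
        assert e2 <= e1

    def test_incomplete_donors_excluded_from_contrast(self):
        """Donors lacking the late passage do not enter the endpoint diff."""
        sheet = _sheet([("a1", "d1", "P3"), ("a2", "d1", "P3"),
                        ("b1", "d1", "P7"), ("b2", "d1", "P7"),
                        ("c1", "d2", "P3"), ("c2", "d2", "P3"),
                        ("e1", "d3", "P3"), ("e2", "d3", "P3"),
                        ("f1", "d3", "P7"), ("f2", "d3", "P7")])
        # d2 has no P7; give it a wild P3 value that would flip the diff
        mat = pd.DataFrame(
            [[6.0, 6.0, 7.0, 7.0, 50.0, 50.0, 6.0, 6.0, 7.0, 7.0]],
            index=["s1"], columns=list(sheet["array_id"]))
        within = pd.Series(0.1, index=["s1"])
        between = pd.Series(0.1, index=["s1"])
        trace = vf.apply_cascade(mat, sheet, within, between, 5.0)
        assert trace.loc["s1", "contrast_mean_diff"] == pytest.approx(1.0)

    def test_too_few_complete_donors_raises(self):
        sheet = _sheet([("a1", "d1", "P3"), ("b1", "d1", "P7")])
        mat = pd.DataFrame([[5.0, 6.0]], index=["s1"], columns=["a1", "b1"])
        with pytest.raises(ValueError, match="donors"):
            vf.apply_cascade(mat, sheet, pd.Series(0.1, index=["s1"]),
                             pd.Series(0.1, index=["s1"]), 5.0)
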