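"""Boltzmann weighting, frequency matrices, information content, conditionals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import groovescan as gs
from groovescan.logos import interaction_deviations, tensor_to_long


class TestBoltzmannWeights:
    def test_equal_energies_give_uniform(self):
        w = gs.boltzmann_weights([1.5, 1.5, 1.5])
        assert np.allclose(w, 1 / 3)

    def test_kT_ln2_gap_gives_two_to_one(self):
        kT = 0.6
        w = gs.boltzmann_weights([0.0, kT * np.log(2)], kT=kT)
        assert np.isclose(w[0] / w[1], 2.0)

    @settings(derandomize=True, max_examples=25)
    @given(
        ddgs=st.lists(st.floats(0, 30), min_size=1, max_size=10),
        shift=st.floats(-20, 20),
    )
    def test_uniform_shift_invariance(self, ddgs, shift):
        w0 = gs.boltzmann_weights(ddgs)
        w1 = gs.boltzmann_weights([d + shift for d in ddgs])
        assert np.allclose(w0, w1, atol=1e-9)

    def test_infinite_temperature_limit_is_uniform(self):
        w = gs.boltzmann_weights([0.0, 1.0, 2.0, 3.0], kT=1e6)
        assert np.allclose(w, 0.25, atol=1e-5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            gs.boltzmann_weights([])

    def test_weights_normalized(self):
        w = gs.boltzmann_weights(np.linspace(0, 5, 17))
        assert np.isclose(w.sum(), 1.0, atol=1e-12)
        assert (w >= 0).all()


class TestFrequencyMatrix:
    def test_single_motif_gives_indicator_columns(self):
        fm = gs.frequency_matrix(["CG"])
        assert np.allclose(fm.loc[1], [0, 1, 0, 0])  # C
        assert np.allclose(fm.loc[2], [0, 0, 1, 0])  # G

    def test_two_motifs_uniform(self):
        fm = gs.frequency_matrix(["AA", "CC"])
        assert np.allclose(fm.loc[1], [0.5, 0.5, 0, 0])
        assert np.allclose(fm.loc[2], [0.5, 0.5, 0, 0])

    def test_weighted_matches_bruteforce_accumulation(self):
        rng = np.random.default_rng(3)
        motifs = gs.enumerate_motifs(3)
        w = rng.random(64)
        w /= w.sum()
        fm = gs.frequency_matrix(motifs, w)
        expected = np.zeros((3, 4))
        base_idx = {b: k for k, b in enumerate("ACGT")}
        for m, wi in zip(motifs, w):
            for j, b in enumerate(m):
                expected[j, base_idx[b]] += wi
        assert np.allclose(np.asarray(fm), expected, atol=1e-12)

    def test_rows_sum_to_one(self, scan_table3):
        bs = gs.select_bound(scan_table3, 1.0)
        w = gs.boltzmann_weights(bs.ddgs())
        fm = gs.frequency_matrix(bs.motifs(), w)
        assert np.allclose(np.asarray(fm).sum(axis=1), 1.0, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gs.frequency_matrix(["AC", "ACG"])


class TestInformationProfile:
    @pytest.mark.parametrize(
        "column,bits",
        [([0.25, 0.25, 0.25, 0.25], 0.0), ([1, 0, 0, 0], 2.0), ([0.5, 0.5, 0, 0], 1.0)],
    )
    def test_closed_form_columns(self, column, bits):
        import pandas as pd

        fm = pd.DataFrame([column], index=[1], columns=list("ACGT"))
        assert np.isclose(gs.information_profile(fm)[0], bits)

    def test_bounded_zero_to_two(self, scan_table3):
        bs = gs.select_bound(scan_table3, 3.0)
        fm = gs.frequency_matrix(bs.motifs())
        ic = gs.information_profile(fm)
        assert (ic >= -1e-12).all() and (ic <= 2 + 1e-12).all()


class TestThresholdSweep:
    def test_whole_table_threshold_equals_full_composition(self, scan_table3):
        tmax = float(scan_table3.ddgs().max())
        series = gs.frequency_vs_threshold(scan_table3, [tmax])
        full = gs.frequency_matrix(scan_table3.motifs())
        assert np.allclose(np.asarray(series[tmax]), np.asarray(full), atol=1e-12)

    def test_zero_threshold_uses_tied_minimum_only(self, scan_table3):
        series = gs.frequency_vs_threshold(scan_table3, [0.0])
        mins = gs.select_bound(scan_table3, 0.0).motifs()
        assert np.allclose(
            np.asarray(series[0.0]), np.asarray(gs.frequency_matrix(mins)), atol=1e-12)

    def test_series_matches_independent_recomputation(self, scan_table3):
        thresholds = [0.5, 1.0, 2.0]
        series = gs.frequency_vs_threshold(scan_table3, thresholds)
        for t in thresholds:
            motifs = [r.motif for r in scan_table3.records if r.ddG <= t]
            assert np.allclose(
                np.asarray(series[t]), np.asarray(gs.frequency_matrix(motifs)), atol=1e-12)

    def test_unsorted_thresholds_rejected(self, scan_table3):
        with pytest.raises(ValueError):
            gs.frequency_vs_threshold(scan_table3, [2.0, 1.0])


class TestConditionalProbabilities:
    def test_hand_counted_two_motif_case(self):
        tensor = gs.conditional_probabilities(["AC", "AG"])
        # P(C at 2 | A at 1) = 0.5
        assert np.isclose(tensor[0, 0, 1, 1], 0.5)
        assert np.isclose(tensor[0, 0, 1, 2], 0.5)  # P(G at 2 | A at 1)

    def test_defined_slices_normalize(self, scan_table3):
        bs = gs.select_bound(scan_table3, 2.0)
        w = gs.boltzmann_weights(bs.ddgs())
        tensor = gs.conditional_probabilities(bs.motifs(), w)
        L = tensor.shape[0]
        for i in range(L):
            for a in range(4):
                for j in range(L):
                    if i == j:
                        continue
                    s = tensor[i, a, j, :]
                    if np.isfinite(s).all():
                        assert np.isclose(s.sum(), 1.0, atol=1e-9)

    def test_undefined_entries_are_nan_not_zero(self):
        # no motif has T at position 1, so conditioning on it is undefined
        tensor = gs.conditional_probabilities(["AC", "AG"])
        assert np.isnan(tensor[0, 3, 1, :]).all()

    def test_chain_rule_on_weighted_ensemble(self, scan_table3):
        bs = gs.select_bound(scan_table3, 2.0)
        w = gs.boltzmann_weights(bs.ddgs())
        motifs = bs.motifs()
        tensor = gs.conditional_probabilities(motifs, w)
        base_idx = {b: k for k, b in enumerate("ACGT")}
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = rng.choice(tensor.shape[0], 2, replace=False)
            a, b = rng.integers(0, 4, 2)
            w_a = sum(wi for m, wi in zip(motifs, w) if base_idx[m[i]] == a)
            w_ab = sum(
                wi for m, wi in zip(motifs, w)
                if base_idx[m[i]] == a and base_idx[m[j]] == b
            )
            p = tensor[i, a, j, b]
            if w_a > 0:
                assert np.isclose(w_ab, w_a * p, atol=1e-12)
            else:
                assert np.isnan(p)

    def test_independent_ensemble_has_vanishing_dependencies(self):
        """Motifs drawn from a product distribution: P(b|a) -> P(b) as n grows."""
        rng = np.random.default_rng(42)
        probs = np.array([[0.5, 0.2, 0.2, 0.1], [0.1, 0.4, 0.4, 0.1], [0.25] * 4])
        bases = np.array(list("ACGT"))

        def draw(n):
            cols = [rng.choice(4, size=n, p=p) for p in probs]
            return ["".join(bases[c[k]] for c in cols) for k in range(n)]

        def max_dev(motifs):
            fm = np.asarray(gs.frequency_matrix(motifs))
            tensor = gs.conditional_probabilities(motifs)
            devs = []
            for i in range(3):
                for a in range(4):
                    for j in range(3):
                        if i == j:
                            continue
                        s = tensor[i, a, j, :]
                        if np.isfinite(s).all():
                            devs.append(np.abs(s - fm[j]).max())
            return max(devs)

        d_small, d_big = max_dev(draw(100)), max_dev(draw(5000))
        assert d_big < 0.1
        assert d_big < d_small


def test_tensor_long_format_and_deviation_report(scan_table3):
    bs = gs.select_bound(scan_table3, 1.0)
    tensor = gs.conditional_probabilities(bs.motifs())
    long = tensor_to_long(tensor)
    assert set(long.columns) == {"i", "a", "j", "b", "P"}
    assert ((long["P"] >= 0) & (long["P"] <= 1)).all()
    report = interaction_deviations(bs.motifs(), report_threshold=0.0)
    assert (report["deviation"] >= 0).all()


def test_render_logo_writes_file(tmp_path, scan_table3):
    bs = gs.select_bound(scan_table3, 3.0)
    fm = gs.frequency_matrix(bs.motifs())
    out = tmp_path / "logo.png"
    from groovescan.logos import render_logo

    render_logo(fm, out)
    assert out.stat().st_size > 0
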