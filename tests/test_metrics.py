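import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from selentropy import (
    AffinityValue,
    CompoundProfile,
    MetricSettings,
    ProfilePanel,
    SelectivityError,
    compute_all_metrics,
    gini_from_inhibition,
    hill_percent_inhibition,
    ka_gini,
    partition_index,
    selectivity_entropy,
    selectivity_score_cutoff,
    selectivity_score_fold,
    weighted_entropy,
)

from conftest import lorenz_area_bruteforce

NM = 1e-9
UM = 1e-6

ka_vectors = st.lists(
    st.floats(min_value=1e3, max_value=1e12), min_size=1, max_size=30
)


class TestSelectivityEntropy:
    @pytest.mark.parametrize(
        ("kas", "expected", "places"),
        [
            ([1e9], 0.0, 10),                      # single target: perfectly selective
            ([1e9, 1e9], 0.69, 2),                 # two equal targets
            ([1e9, 1e6], 0.0079, 4),               # 1000x weaker second target
            ([1e9] + [1e8] * 10, 1.84, 2),         # one potent + ten 10x weaker
            ([1e9] * 3, math.log(3), 10),          # exact ln 3, not the rounded 1.08
        ],
    )
    def test_worked_examples(self, kas, expected, places):
        assert round(selectivity_entropy(kas).s_sel, places) == round(expected, places)

    def test_five_target_mixed_profile_matches_direct_evaluation(self):
        # independent arithmetic straight from the definition
        kas = [1e9] * 3 + [1e6] * 2
        total = sum(kas)
        expected = -sum((k / total) * math.log(k / total) for k in kas)
        assert selectivity_entropy(kas).s_sel == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.104, abs=5e-4)
        assert expected < math.log(5)  # entropy of 5 states is bounded by ln 5

    def test_fractions_sum_to_one_and_bound(self):
        res = selectivity_entropy([5e8, 3e8, 0.0, 2e8])
        assert res.n_active == 3
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= res.s_sel <= math.log(res.n_active)

    def test_all_zero_is_no_binding_error(self):
        with pytest.raises(SelectivityError, match="no binding"):
            selectivity_entropy([0.0, 0.0])

    @given(ka_vectors, st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, kas, c):
        base = selectivity_entropy(kas).s_sel
        scaled = selectivity_entropy([c * k for k in kas]).s_sel
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_cheng_prusoff_factor_two_drops_out(self):
        # IC50-at-KM,ATP = 2x Kd: the common factor cancels in the fractions
        kds = [1 * NM, 30 * NM, 2 * UM]
        s_kd = selectivity_entropy([1 / k for k in kds]).s_sel
        s_ic50 = selectivity_entropy([1 / (2 * k) for k in kds]).s_sel
        assert s_ic50 == pytest.approx(s_kd, rel=1e-12)

    @pytest.mark.parametrize("m", range(1, 51))
    def test_equal_potency_limit_is_ln_m(self, m):
        res = selectivity_entropy([1e9] * m)
        assert res.s_sel == pytest.approx(math.log(m), abs=1e-12)
        if m > 1:
            assert ka_gini([1e9] * m) == pytest.approx(0.0, abs=1e-12)

    @given(ka_vectors, st.integers(min_value=1, max_value=20))
    def test_null_target_invariance(self, kas, n_zeros):
        base = selectivity_entropy(kas).s_sel
        padded = selectivity_entropy(list(kas) + [0.0] * n_zeros).s_sel
        assert padded == pytest.approx(base, rel=1e-12, abs=1e-12)

    @given(ka_vectors)
    def test_permutation_invariance(self, kas):
        rng = np.random.default_rng(0)
        shuffled = list(kas)
        rng.shuffle(shuffled)
        assert selectivity_entropy(shuffled).s_sel == pytest.approx(
            selectivity_entropy(kas).s_sel, rel=1e-12, abs=1e-12
        )

    @given(ka_vectors)
    def test_entropy_bounded_below_by_neg_log_pmax(self, kas):
        s = selectivity_entropy(kas).s_sel
        pmax = partition_index(kas)
        assert s >= -math.log(pmax) - 1e-9


class TestWeightedEntropy:
    def test_unit_weights_reduce_to_unweighted(self):
        kas = [1e9, 3e8, 1e6]
        assert weighted_entropy(kas, [1.0] * 3).s_sel == pytest.approx(
            selectivity_entropy(kas).s_sel, abs=1e-15
        )

    def test_zero_weight_removes_a_state(self):
        assert weighted_entropy([1e9, 1e9], [1.0, 0.0]).s_sel == 0.0

    def test_weights_can_equalize_unequal_affinities(self):
        # w*Ka = {1e9, 1e9}: two equally occupied states
        assert weighted_entropy([1e9, 1e6], [1.0, 1000.0]).s_sel == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_length_mismatch_and_zero_sum_errors(self):
        with pytest.raises(SelectivityError, match="weights"):
            weighted_entropy([1e9], [1.0, 2.0])
        with pytest.raises(SelectivityError, match="no binding"):
            weighted_entropy([1e9, 1e9], [0.0, 0.0])


class TestPartitionIndex:
    @pytest.mark.parametrize(
        ("kas", "expected"),
        [
            ([1e9, 1e9], 0.5),            # inhibitor B: two equal targets
            ([1e9], 1.0),                 # single state
            ([1e9] + [1e8] * 10, 0.5),    # inhibitor A: same Pmax, very different profile
        ],
    )
    def test_reference_fraction(self, kas, expected):
        assert partition_index(kas) == pytest.approx(expected, abs=1e-12)

    def test_explicit_reference_overrides_max(self):
        assert partition_index([1e9, 1e6], reference=1) == pytest.approx(1e6 / 1.001e9)

    def test_first_index_wins_ties(self):
        assert partition_index([2e9, 2e9, 1e9]) == partition_index([2e9, 2e9, 1e9], reference=0)

    def test_errors(self):
        with pytest.raises(SelectivityError, match="out of range"):
            partition_index([1e9], reference=5)
        with pytest.raises(SelectivityError, match="no binding"):
            partition_index([0.0])

    @given(ka_vectors, st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, kas, c):
        assert partition_index([c * k for k in kas]) == pytest.approx(
            partition_index(kas), rel=1e-9
        )


class TestSelectivityScores:
    @pytest.mark.parametrize(
        ("kds", "cutoff", "n", "expected"),
        [
            ([1 * NM, 1 * UM], 3 * UM, 2, 1.0),
            ([1 * NM, 10 * UM], 3 * UM, 2, 0.5),
            ([1 * NM], 3 * UM, 290, 1 / 290),
        ],
    )
    def test_cutoff_score(self, kds, cutoff, n, expected):
        assert selectivity_score_cutoff(kds, cutoff, n) == pytest.approx(expected)

    def test_censored_entries_never_count_as_hit(self):
        affs = [AffinityValue.measured(1 * NM), AffinityValue.above_limit(10 * UM)]
        assert selectivity_score_cutoff(affs, 3 * UM, 2) == 0.5

    def test_cutoff_is_not_scale_invariant(self):
        kds = [1 * NM, 1 * UM]
        s1 = selectivity_score_cutoff(kds, 3 * UM, 2)
        s2 = selectivity_score_cutoff([10 * k for k in kds], 3 * UM, 2)
        assert s1 != s2

    @given(st.lists(st.floats(min_value=1e-10, max_value=1e-4), min_size=1, max_size=20))
    def test_cutoff_monotone_in_cutoff(self, kds):
        cuts = [1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3]
        scores = [selectivity_score_cutoff(kds, c, len(kds)) for c in cuts]
        assert scores == sorted(scores)

    @pytest.mark.parametrize(
        ("kds", "expected"),
        [
            ([1 * NM, 1 * UM], 0.5),              # only the reference within 10x
            ([1 * NM, 1 * NM], 1.0),
            ([1 * NM, 9 * NM, 11 * NM], 2 / 3),   # boundary convention: <= 10x counts
        ],
    )
    def test_fold_score(self, kds, expected):
        assert selectivity_score_fold(kds, 10.0, len(kds)) == pytest.approx(expected)

    def test_fold_score_needs_a_measurement(self):
        with pytest.raises(SelectivityError, match="no measured"):
            selectivity_score_fold([AffinityValue.missing()], 10.0, 1)

    def test_reference_always_counts(self):
        # S(10x) can never be zero: the reference target is itself a hit
        assert selectivity_score_fold([1 * NM], 10.0, 290) == pytest.approx(1 / 290)


class TestHillConversion:
    def test_kd_equal_to_concentration_gives_half_inhibition(self):
        assert hill_percent_inhibition(1 * UM, 1 * UM) == pytest.approx(50.0)

    def test_three_log_units_apart(self):
        assert hill_percent_inhibition(1 * NM, 1 * UM) == pytest.approx(100 / (1 + 1e-3))
        assert hill_percent_inhibition(1 * UM, 1 * NM) == pytest.approx(100 / (1 + 1e3))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(SelectivityError):
            hill_percent_inhibition(0.0, 1e-6)


class TestGini:
    @pytest.mark.parametrize("n", [2, 3, 7, 50])
    def test_equal_values_give_zero(self, n):
        assert gini_from_inhibition([40.0] * n) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 100, 290])
    def test_single_spike_closed_form(self, n):
        # all signal on one target: trapezoid Lorenz gives (n-1)/n
        values = [100.0] + [0.0] * (n - 1)
        assert gini_from_inhibition(values) == pytest.approx((n - 1) / n, abs=1e-12)

    def test_half_and_half(self):
        assert gini_from_inhibition([50.0, 50.0, 0.0, 0.0]) == pytest.approx(0.5, abs=1e-12)

    def test_all_zero_is_an_error(self):
        with pytest.raises(SelectivityError, match="no inhibition"):
            gini_from_inhibition([0.0, 0.0])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=1, max_size=5)
        .filter(lambda v: sum(v) > 1e-6)
    )
    def test_matches_geometric_oracle_on_small_panels(self, values):
        expected = 1.0 - 2.0 * lorenz_area_bruteforce(values)
        assert gini_from_inhibition(values) == pytest.approx(expected, abs=1e-9)

    def test_ka_gini_single_binder_in_large_panel(self):
        assert ka_gini([1e9] + [0.0] * 99) == pytest.approx(0.99, abs=1e-12)
        assert ka_gini([1e9] + [0.0] * 289) == pytest.approx(289 / 290, abs=1e-12)

    @given(ka_vectors, st.floats(min_value=1e-3, max_value=1e3))
    def test_ka_gini_scale_invariant(self, kas, c):
        assert ka_gini([c * k for k in kas]) == pytest.approx(ka_gini(kas), rel=1e-9, abs=1e-9)

    @given(ka_vectors, st.integers(min_value=1, max_value=10))
    def test_null_targets_increase_ka_gini(self, kas, n_zeros):
        assert ka_gini(list(kas) + [0.0] * n_zeros) >= ka_gini(kas) - 1e-12


def _panel(rows: dict[str, list[float | None]], n_targets: int) -> ProfilePanel:
    targets = [f"T{i}" for i in range(n_targets)]
    compounds = []
    for cid, kds in rows.items():
        aff = {
            t: AffinityValue.measured(kd) if kd is not None else AffinityValue.missing()
            for t, kd in zip(targets, kds)
        }
        compounds.append(CompoundProfile(cid, aff))
    return ProfilePanel("test", targets, compounds)


class TestComputeAllMetrics:
    def test_single_potent_target_in_two_target_panel(self):
        panel = _panel({"c1": [1 * NM, None], "c2": [1 * NM, 2 * NM]}, 2)
        reports = {r.compound_id: r for r in compute_all_metrics(panel)}
        r = reports["c1"]
        assert r.entries["entropy"] == pytest.approx(0.0, abs=1e-12)
        assert r.entries["pmax"] == pytest.approx(1.0)
        assert r.entries["s_cutoff"] == pytest.approx(0.5)
        assert r.n_targets_used == 1

    def test_identical_compounds_tie_broken_by_input_order(self):
        panel = _panel({"first": [1 * NM, 5 * NM], "second": [1 * NM, 5 * NM]}, 2)
        reports = compute_all_metrics(panel)
        assert reports[0].entries == reports[1].entries
        for m in reports[0].ranks:
            assert reports[0].ranks[m] == 1
            assert reports[1].ranks[m] == 2

    def test_ranks_are_a_permutation_and_oriented(self):
        panel = _panel(
            {
                "selective": [1 * NM, None, None, None],
                "medium": [1 * NM, 50 * NM, None, None],
                "promiscuous": [1 * NM, 1 * NM, 1 * NM, 1 * NM],
            },
            4,
        )
        reports = compute_all_metrics(panel)
        for m in reports[0].ranks:
            assert sorted(r.ranks[m] for r in reports) == [1, 2, 3]
        by_id = {r.compound_id: r for r in reports}
        # every metric must call the single-target binder most selective
        for m in ("entropy", "pmax", "ka_gini", "gini", "s_fold"):
            assert by_id["selective"].ranks[m] == 1, m
            assert by_id["promiscuous"].ranks[m] == 3, m

    def test_weighted_panel_uses_weighted_entropy(self):
        targets = ["T0", "T1"]
        compounds = [
            CompoundProfile("c", {"T0": AffinityValue.measured(1 * NM),
                                  "T1": AffinityValue.measured(1 * UM)})
        ]
        panel = ProfilePanel("w", targets, compounds,
                             target_weights={"T0": 1.0, "T1": 1000.0})
        (report,) = compute_all_metrics(panel)
        assert report.entries["entropy"] == pytest.approx(math.log(2), abs=1e-12)

    def test_error_annotated_with_compound_id(self):
        targets = ["T0"]
        compounds = [CompoundProfile("dead", {"T0": AffinityValue.missing()})]
        panel = ProfilePanel("p", targets, compounds)
        with pytest.raises(SelectivityError, match="dead"):
            compute_all_metrics(panel)

    def test_gini_concentration_changes_gini_only(self):
        panel = _panel({"c1": [1 * NM, 30 * NM], "c2": [1 * NM, 1 * UM]}, 2)
        base = compute_all_metrics(panel, MetricSettings())
        alt = compute_all_metrics(
            panel, MetricSettings(gini_test_concentration=1e-7)
        )
        for rb, ra in zip(base, alt):
            assert rb.entries["gini"] != ra.entries["gini"]
            for m in ("entropy", "pmax", "ka_gini", "s_cutoff", "s_fold"):
                assert rb.entries[m] == ra.entries[m]
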