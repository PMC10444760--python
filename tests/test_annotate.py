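import math
from itertools import combinations

import numpy as np
import pytest

from tcrsafe.annotate import (
    BinderClassConfig,
    DoseResponse,
    MinigeneConstruct,
    annotate_candidates,
    classify_activation,
    classify_binder,
    compare_groups,
    correlate,
    design_minigene,
    design_trimer_minigene,
    screen_dose_response,
    tumor_volume,
)
from tcrsafe.core import EpitopeContext, Peptide
from tcrsafe.io_formats import BindingPrediction
from tcrsafe.proteome_scan import CandidatePeptide


def prediction(rank, affinity=100.0):
    return BindingPrediction("SLLMWITQC", "HLA-A*02:01", affinity, rank)


class TestBinderClassification:
    @pytest.mark.parametrize(
        "rank, expected",
        [
            (0.4, "strong"),
            (0.49, "strong"),
            (0.5, "weak"),    # strict < at the strong boundary
            (1.9, "weak"),
            (2.0, "none"),    # strict < at the weak boundary
            (45.0, "none"),
        ],
    )
    def test_rank_thresholds_strict(self, rank, expected):
        assert classify_binder(prediction(rank)) == expected

    def test_monotone_in_rank(self, rng):
        order = {"strong": 0, "weak": 1, "none": 2}
        ranks = sorted(rng.uniform(0.01, 10, size=50))
        classes = [order[classify_binder(prediction(r))] for r in ranks]
        assert classes == sorted(classes)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BinderClassConfig(strong_rank_cutoff=2.0, weak_rank_cutoff=0.5)


class TestActivationCall:
    @pytest.mark.parametrize(
        "response, expected",
        [
            (0.10, "activating"),   # inclusive boundary: 10% or more
            (0.099, "non_activating"),
            (1.0, "activating"),
            (0.0, "non_activating"),
        ],
    )
    def test_ten_percent_rule(self, response, expected):
        assert classify_activation(response) == expected

    def test_negative_response_rejected(self):
        with pytest.raises(ValueError):
            classify_activation(-0.1)


class TestDoseResponseScreen:
    def test_flat_zero_curve_never_activates(self):
        dr = DoseResponse(Peptide("SLLMWITQC"), [(1e-9, 0.0), (1e-8, 0.0), (1e-7, 0.0)])
        calls, overall = screen_dose_response(dr)
        assert overall == "non_activating"
        assert all(call == "non_activating" for _, call in calls)

    def test_saturated_curve_activates_everywhere(self):
        dr = DoseResponse(Peptide("SLLMWITQC"), [(1e-9, 1.0), (1e-7, 1.0)])
        calls, overall = screen_dose_response(dr)
        assert overall == "activating"
        assert all(call == "activating" for _, call in calls)

    def test_sigmoid_crossing_cutoff_flips_exactly_once(self):
        concs = [1e-10, 1e-9, 1e-8, 1e-7, 1e-6]
        responses = [1.0 / (1.0 + (5e-9 / c)) for c in concs]  # crosses 0.10 once
        dr = DoseResponse(Peptide("SLLMWITQC"), list(zip(concs, responses)))
        calls, overall = screen_dose_response(dr, screen_concentration=1e-6)
        flips = sum(
            1 for (_, a), (_, b) in zip(calls, calls[1:]) if a != b
        )
        assert flips == 1
        assert overall == "activating"

    def test_absent_screen_concentration_lists_available(self):
        dr = DoseResponse(Peptide("SLLMWITQC"), [(1e-9, 0.5)])
        with pytest.raises(ValueError, match="1e-09"):
            screen_dose_response(dr, screen_concentration=1e-7)


def enumeration_p_value(a, b):
    """Independent oracle: exact two-sided p via rank-sum enumeration."""
    pooled = sorted(a + b)
    n1, n2 = len(a), len(b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    count = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = sum(i + 1 for i in idx) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestCompareGroups:
    def test_printed_two_vs_two_example(self):
        result = compare_groups([1, 2], [3, 4])
        assert result.method == "exact"
        assert result.p_two_sided == pytest.approx(1 / 3)
        assert result.U == 0

    def test_identical_tied_groups_give_p_one(self):
        result = compare_groups([5, 5], [5, 5])
        assert result.method == "normal_approximation"
        assert result.p_two_sided == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])

    def test_exact_on_all_two_vs_two_splits(self):
        values = [1, 2, 3, 4]
        for idx in combinations(range(4), 2):
            a = [values[i] for i in idx]
            b = [values[i] for i in range(4) if i not in idx]
            result = compare_groups(a, b)
            assert result.method == "exact"
            assert result.p_two_sided == pytest.approx(enumeration_p_value(a, b))

    def test_symmetric_under_group_swap(self, rng):
        for _ in range(20):
            a = list(rng.choice(1000, size=4, replace=False))
            b = list(rng.choice(2000, size=5, replace=False) + 1000)
            assert compare_groups(a, b).p_two_sided == pytest.approx(
                compare_groups(b, a).p_two_sided
            )

    def test_invariant_under_monotone_transform(self, rng):
        a = list(rng.uniform(0, 1, size=5))
        b = list(rng.uniform(0.2, 1.2, size=6))
        p_raw = compare_groups(a, b).p_two_sided
        p_exp = compare_groups([math.exp(x) for x in a], [math.exp(x) for x in b]).p_two_sided
        assert p_raw == pytest.approx(p_exp)

    def test_exact_and_approximate_agree_on_untied_tens(self, rng):
        for _ in range(10):
            pooled = rng.choice(10_000, size=20, replace=False).astype(float)
            a, b = list(pooled[:10]), list(pooled[10:])
            exact = compare_groups(a, b, method="exact")
            approx = compare_groups(a, b, method="normal_approximation")
            assert abs(exact.p_two_sided - approx.p_two_sided) < 0.02
            assert exact.p_two_sided == pytest.approx(enumeration_p_value(a, b))

    def test_forced_exact_on_tied_data_rejected(self):
        with pytest.raises(ValueError, match="untied"):
            compare_groups([1, 1], [2, 3], method="exact")

    def test_large_sample_uses_normal_approximation(self, rng):
        a = list(rng.normal(0, 1, size=15))
        b = list(rng.normal(1, 1, size=15))
        result = compare_groups(a, b)
        assert result.method == "normal_approximation"
        assert 0 < result.p_two_sided <= 1


class TestCorrelate:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert correlate(x, [2 * v for v in x]) == pytest.approx(1.0)
        assert correlate(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(0, 1, size=50)
        y = 0.7 * x + rng.normal(0, 0.5, size=50)
        r = correlate(list(x), list(y))
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_spearman_option(self, rng):
        x = list(rng.normal(0, 1, size=30))
        y = [v**3 for v in x]  # monotone but nonlinear
        assert correlate(x, y, method="spearman") == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0, 3.0], [1.0, 2.0])


class TestMinigeneDesign:
    def _context(self, offset, prot_len, epitope="SLLMWITQC"):
        prot = (
            "ACDEFGHIKLMNPQRSTVWY" * 10
        )[:offset] + epitope + ("ACDEFGHIKLMNPQRSTVWY" * 10)[: prot_len - offset - len(epitope)]
        return EpitopeContext("P1", prot, Peptide(epitope), offset)

    def test_centered_epitope_default_layout(self):
        ctx = self._context(offset=20, prot_len=60)
        construct = design_minigene(ctx)
        assert construct.total_length == 30
        assert construct.epitope_start == 10
        assert not construct.truncated

    def test_near_n_terminus_deficit_taken_downstream(self):
        ctx = self._context(offset=3, prot_len=60)
        construct = design_minigene(ctx)
        assert construct.total_length == 30
        assert construct.epitope_start == 3

    def test_near_c_terminus_deficit_taken_upstream(self):
        ctx = self._context(offset=48, prot_len=60)  # only 3 downstream residues
        construct = design_minigene(ctx)
        assert construct.total_length == 30
        assert construct.epitope_start == 18

    def test_protein_shorter_than_construct_is_flagged(self):
        ctx = EpitopeContext("P1", "SLLMWITQC", Peptide("SLLMWITQC"), 0)
        construct = design_minigene(ctx)
        assert construct.aa_sequence == "SLLMWITQC"
        assert construct.total_length == 9
        assert construct.truncated

    def test_epitope_verbatim_with_natural_flanks(self, rng):
        for _ in range(20):
            prot_len = int(rng.integers(30, 80))
            offset = int(rng.integers(0, prot_len - 9))
            ctx = self._context(offset=offset, prot_len=prot_len)
            construct = design_minigene(ctx)
            s = construct.epitope_start
            assert construct.aa_sequence[s : s + 9] == str(ctx.epitope)
            start_in_prot = ctx.epitope_offset - s
            assert (
                ctx.protein_sequence[start_in_prot : start_in_prot + construct.total_length]
                == construct.aa_sequence
            )

    def test_tag_is_metadata_not_sequence(self):
        ctx = self._context(offset=20, prot_len=60)
        construct = design_minigene(ctx, tag="GFP")
        assert construct.tag == "GFP"
        assert "GFP" != construct.aa_sequence[-3:]
        assert construct.total_length == 30

    def test_total_length_shorter_than_epitope_rejected(self):
        ctx = self._context(offset=20, prot_len=60)
        with pytest.raises(ValueError):
            design_minigene(ctx, total_length=8)


class TestTrimerMinigene:
    def test_default_aay_linker(self):
        assert design_trimer_minigene("SLFLGILSV") == "SLFLGILSVAAY"

    def test_empty_linker_returns_epitope(self):
        assert design_trimer_minigene("SLFLGILSV", linker="") == "SLFLGILSV"

    def test_linker_exactly_once_at_end(self):
        out = design_trimer_minigene("SLFLGILSV")
        assert out.count("AAY") == 1
        assert out.endswith("AAY")


class TestTumorVolume:
    @pytest.mark.parametrize(
        "dims, expected",
        [((1, 1, 1), math.pi / 6), ((10, 5, 3), 78.5398), ((0, 5, 3), 0.0)],
    )
    def test_ellipsoid_formula(self, dims, expected):
        assert tumor_volume(*dims) == pytest.approx(expected, abs=1e-4)

    def test_negative_dimension_rejected(self):
        with pytest.raises(ValueError):
            tumor_volume(-1, 1, 1)


class TestAnnotateCandidates:
    def test_predictions_and_activation_filled_in(self):
        cands = [CandidatePeptide(Peptide("FLTLWLTQV"), [("P1", 0)], 5)]
        preds = [BindingPrediction("FLTLWLTQV", "HLA-A*02:01", 6.1, 0.3)]
        annotate_candidates(cands, preds, activation_responses={"FLTLWLTQV": 0.95})
        assert cands[0].binder_class == "strong"
        assert cands[0].predicted_affinity_nM == 6.1
        assert cands[0].activation == "activating"

    def test_unmatched_candidates_stay_untested(self):
        cands = [CandidatePeptide(Peptide("AAAAAAAAA"), [("P1", 0)], 7)]
        annotate_candidates(cands, [])
        assert cands[0].binder_class is None
        assert cands[0].activation == "untested"
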