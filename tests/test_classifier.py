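"""Weighted Tanimoto-sum scoring, decision rule and explanations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ototox.chem_io import CompoundSet, Label, parse_compound
from ototox.classifier import (
    ModelBuildError,
    WeightMode,
    WeightScheme,
    build_model,
    classify,
    explain,
    load_model,
    save_model,
    score_compound,
)
from ototox.fingerprints import FingerprintParams

from conftest import SMALL_PARAMS, make_synth_compound


def synth_model(oto_specs, non_specs, weights=None, params=SMALL_PARAMS):
    """Model over injected-fingerprint compounds: specs are (id, bits)."""
    otos = CompoundSet(
        [make_synth_compound(i, b, Label.OTOTOXIN, params) for i, b in oto_specs]
    )
    nons = CompoundSet(
        [make_synth_compound(i, b, Label.NON_OTOTOXIN, params) for i, b in non_specs]
    )
    return build_model(otos, nons, weights, params)


class TestWeightScheme:
    def test_class_normalized_resolves_to_inverse_class_sizes(self):
        alpha, beta = WeightScheme().resolve(70, 237)
        assert np.allclose(alpha, 1 / 70) and len(alpha) == 70
        assert np.allclose(beta, -1 / 237) and len(beta) == 237

    def test_singleton_classes_give_unit_weights(self):
        alpha, beta = WeightScheme().resolve(1, 1)
        assert alpha.tolist() == [1.0] and beta.tolist() == [-1.0]

    def test_custom_sign_convention_enforced(self):
        bad = WeightScheme(
            mode=WeightMode.CUSTOM, alpha=(1.0, -0.5), beta=(-1.0,)
        )
        with pytest.raises(ValueError, match="positive"):
            bad.resolve(2, 1)


class TestBuildModel:
    def test_overlap_between_classes_is_an_error(self):
        otos = CompoundSet([parse_compound("CCO", "ethanol", Label.OTOTOXIN)])
        nons = CompoundSet(
            [
                parse_compound("OCC", "ethanol-again", Label.NON_OTOTOXIN),
                parse_compound("CO", "methanol", Label.NON_OTOTOXIN),
            ]
        )
        with pytest.raises(ModelBuildError, match="ethanol"):
            build_model(otos, nons)

    def test_empty_class_is_an_error(self):
        otos = CompoundSet([parse_compound("CCO", "e", Label.OTOTOXIN)])
        with pytest.raises(ModelBuildError):
            build_model(otos, CompoundSet([]))

    def test_mislabeled_member_is_an_error(self):
        otos = CompoundSet([parse_compound("CCO", "e", Label.NON_OTOTOXIN)])
        nons = CompoundSet([parse_compound("CO", "m", Label.NON_OTOTOXIN)])
        with pytest.raises(ModelBuildError, match="labeled"):
            build_model(otos, nons)

    def test_literature_singleton_model(self):
        """One ototoxin vs one non-ototoxin: class-normalized weights are +-1."""
        from ototox.fixtures import LITERATURE_COMPOUNDS

        kana, _ = LITERATURE_COMPOUNDS["kanamycin"]
        dhm, _ = LITERATURE_COMPOUNDS["dihydromyricetin"]
        model = build_model(
            CompoundSet([parse_compound(kana, "kanamycin", Label.OTOTOXIN)]),
            CompoundSet([parse_compound(dhm, "dihydromyricetin", Label.NON_OTOTOXIN)]),
        )
        alpha, beta = model.resolved_weights()
        assert alpha.tolist() == [1.0] and beta.tolist() == [-1.0]


class TestScoreCompound:
    def test_identity_query_scores_plus_one(self):
        model = synth_model([("x", {1, 2, 3})], [("y", {10, 11, 12})])
        query = make_synth_compound("q", {1, 2, 3}, Label.UNKNOWN)
        pred = score_compound(query, model)
        assert pred.score == pytest.approx(1.0, abs=1e-12)
        assert pred.predicted_label is Label.OTOTOXIN
        assert pred.in_training_set is False  # different synthetic identity

    def test_symmetric_classes_cancel_to_zero_tie_is_ototoxin(self):
        # both references share exactly half their bits with the query
        model = synth_model([("o", {1, 2, 3, 4})], [("n", {1, 2, 5, 6})])
        query = make_synth_compound("q", {1, 2}, Label.UNKNOWN)
        pred = score_compound(query, model)
        assert pred.score == pytest.approx(0.0, abs=1e-12)
        assert pred.predicted_label is Label.OTOTOXIN

    def test_explicit_bitset_example_uniform_weights(self):
        model = synth_model(
            [("o", {1, 2, 3})],
            [("n", {7, 8, 9})],
            weights=WeightScheme(mode=WeightMode.UNIFORM),
        )
        query = make_synth_compound("q", {2, 3, 4}, Label.UNKNOWN)
        pred = score_compound(query, model)
        assert pred.oto_sum == pytest.approx(0.5, abs=1e-12)
        assert pred.non_oto_sum == pytest.approx(0.0, abs=1e-12)
        assert pred.score == pytest.approx(0.5, abs=1e-12)

    def test_score_is_sum_of_class_sums(self, separable_population):
        from ototox.fingerprints import FingerprintParams

        otos, nons, _ = separable_population
        model = build_model(otos, nons, fp_params=FingerprintParams())
        for c in list(otos)[:5] + list(nons)[:5]:
            pred = score_compound(c, model)
            assert pred.score == pytest.approx(
                pred.oto_sum + pred.non_oto_sum, abs=1e-9
            )
            assert pred.in_training_set

    def test_in_training_set_flag_on_structural_identity(self):
        otos = CompoundSet([parse_compound("CCO", "ethanol", Label.OTOTOXIN)])
        nons = CompoundSet([parse_compound("c1ccccc1", "benzene", Label.NON_OTOTOXIN)])
        model = build_model(otos, nons)
        pred = score_compound(parse_compound("OCC", "query"), model)
        assert pred.in_training_set
        assert pred.predicted_label is Label.OTOTOXIN


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.2, Label.OTOTOXIN), (-0.2, Label.NON_OTOTOXIN), (0.0, Label.OTOTOXIN)],
    )
    def test_sign_rule(self, score, expected):
        assert classify(score) is expected

    @pytest.mark.parametrize("bad", [math.nan, math.inf, -math.inf])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError):
            classify(bad)


class TestExplain:
    def test_identity_example_top_contribution(self):
        model = synth_model([("x", {1, 2, 3})], [("y", {10, 11, 12})])
        pred = score_compound(
            make_synth_compound("q", {1, 2, 3}, Label.UNKNOWN), model
        )
        table = explain(pred, k=1)
        assert table[0][0] == "x"
        assert table[0][2] == pytest.approx(1.0)
        assert table[0][3] == pytest.approx(1.0)

    def test_k_larger_than_reference_count_clamps(self):
        model = synth_model([("x", {1, 2})], [("y", {5, 6})])
        pred = score_compound(
            make_synth_compound("q", {1, 2}, Label.UNKNOWN), model, k_neighbors=99
        )
        assert len(explain(pred, k=99)) == 2

    def test_equal_contributions_ordered_by_id(self):
        model = synth_model(
            [("b-ref", {1, 2}), ("a-ref", {1, 2})],
            [("z", {40, 41})],
        )
        pred = score_compound(
            make_synth_compound("q", {1, 2}, Label.UNKNOWN), model
        )
        table = explain(pred, k=2)
        oto_rows = [r for r in table if r[1] is Label.OTOTOXIN]
        assert [r[0] for r in oto_rows] == ["a-ref", "b-ref"]

    def test_nonpositive_k_rejected(self):
        model = synth_model([("x", {1})], [("y", {2})])
        pred = score_compound(make_synth_compound("q", {1}, Label.UNKNOWN), model)
        with pytest.raises(ValueError):
            explain(pred, k=0)


bitsets = st.frozensets(st.integers(min_value=0, max_value=63), min_size=1, max_size=20)


class TestScoreProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        q=bitsets,
        o=bitsets,
        n=bitsets,
        k=st.floats(min_value=0.01, max_value=100, allow_nan=False),
    )
    def test_positive_scaling_never_changes_label(self, q, o, n, k):
        base = WeightScheme(mode=WeightMode.CUSTOM, alpha=(1.0,), beta=(-1.0,))
        scaled = WeightScheme(mode=WeightMode.CUSTOM, alpha=(k,), beta=(-k,))
        m1 = synth_model([("o", o)], [("n", n)], weights=base)
        m2 = synth_model([("o", o)], [("n", n)], weights=scaled)
        query = make_synth_compound("q", q, Label.UNKNOWN)
        p1, p2 = score_compound(query, m1), score_compound(query, m2)
        assert p2.score == pytest.approx(k * p1.score, rel=1e-9, abs=1e-12)
        assert p1.predicted_label is p2.predicted_label

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(q=bitsets, o=bitsets, n=bitsets)
    def test_zero_similarity_reference_is_irrelevant(self, q, o, n):
        """Under UNIFORM weights, adding a reference disjoint from the query
        leaves the score unchanged."""
        uniform = WeightScheme(mode=WeightMode.UNIFORM)
        query = make_synth_compound("q", q, Label.UNKNOWN)
        m1 = synth_model([("o", o)], [("n", n)], weights=uniform)
        # a reference using only bits the query never touches
        far = set(range(64)) - q
        if len(far) < 2:
            return
        far_bits = set(sorted(far)[:2])
        m2 = synth_model([("o", o), ("o2", far_bits)], [("n", n)], weights=uniform)
        s1 = score_compound(query, m1).score
        s2 = score_compound(query, m2).score
        assert s2 == pytest.approx(s1, abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(q=bitsets, o=bitsets, n=bitsets)
    def test_monotone_in_single_ototoxin_similarity(self, q, o, n):
        """Pulling one ototoxin reference strictly closer to the query (in
        Tanimoto) never decreases the score."""
        uniform = WeightScheme(mode=WeightMode.UNIFORM)
        query = make_synth_compound("q", q, Label.UNKNOWN)
        gain = q - o
        if not gain:
            return
        # swap one non-shared ref bit for a query bit, or just add a query bit
        closer = o | {min(gain)}
        from ototox.fingerprints import tanimoto
        from ototox.fingerprints import Fingerprint

        t_before = tanimoto(
            make_synth_compound("a", q, Label.UNKNOWN).fingerprint,
            make_synth_compound("b", o, Label.UNKNOWN).fingerprint,
        )
        t_after = tanimoto(
            make_synth_compound("a", q, Label.UNKNOWN).fingerprint,
            make_synth_compound("b", closer, Label.UNKNOWN).fingerprint,
        )
        assert t_after >= t_before
        m1 = synth_model([("o", o)], [("n", n)], weights=uniform)
        m2 = synth_model([("o", closer)], [("n", n)], weights=uniform)
        s1 = score_compound(query, m1).score
        s2 = score_compound(query, m2).score
        assert s2 >= s1 - 1e-12


class TestSelfRetrieval:
    def test_training_ototoxins_score_positive_in_balanced_model(self):
        """Class-normalized, |O| == |N|, all off-diagonal similarities < 1:
        every training ototoxin retrieves itself with a positive score."""
        from ototox.synthetic import SyntheticSpec, generate_population

        spec = SyntheticSpec(
            n_oto=20, n_non=20, separation=0.5, flip_noise=0.1, seed=3
        )
        otos, nons, _ = generate_population(spec)
        model = build_model(otos, nons, fp_params=FingerprintParams())
        for c in otos:
            pred = score_compound(c, model)
            assert pred.score > 0
            assert pred.in_training_set


class TestPersistence:
    def test_save_load_reproduces_scores(self, tmp_path, labeled_compound_sets):
        otos, nons = labeled_compound_sets
        model = build_model(otos, nons)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.digest() == model.digest()
        query = parse_compound("NCC(O)C(O)CO", "probe")
        assert score_compound(query, loaded).score == pytest.approx(
            score_compound(query, model).score, abs=1e-12
        )

    def test_missing_model_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope.json")
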