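"""Blocking, clue evaluation, maxent scoring, thresholds and assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from perilink import linkage_engine as le
from perilink import pipeline
from perilink.synthetic_cohort import CohortParams, ErrorModel, generate_cohort

from conftest import zero_error_params


def _stream(rows, **common):
    """Minimal standardized stream from dicts of comparator columns."""
    defaults = {
        "given": "", "surname": "", "alias": "", "given_sx": "", "given_ny": "",
        "surname_sx": "", "surname_ny": "", "dob": "", "dob_year": "",
        "dob_month": "", "dob_day": "", "sex": "", "address": "", "country": "",
        "mrn": "", "hospital_code": "", "event_ord": np.nan,
        "admission_ord": np.nan, "separation_ord": np.nan,
        "birth_order": np.nan, "stratum": "singleton",
    }
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(common)
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# blocking

class TestBlocking:
    SPEC = le.BlockingSpec(keys=(le.BlockingKey("dob", ("dob",)),))

    def test_shared_key_crosses_streams(self):
        a = _stream([{"record_id": "a1", "dob": "2001-01-01"},
                     {"record_id": "a2", "dob": "2001-01-01"}])
        b = _stream([{"record_id": "b1", "dob": "2001-01-01"}])
        pairs = le.make_blocks(a, b, self.SPEC)
        assert set(zip(pairs.record_id_a, pairs.record_id_b)) == {("a1", "b1"), ("a2", "b1")}

    def test_empty_stream_gives_empty_pairs(self):
        a = _stream([{"record_id": "a1", "dob": "2001-01-01"}])
        pairs = le.make_blocks(a, a.iloc[:0], self.SPEC)
        assert len(pairs) == 0

    def test_missing_key_values_do_not_block(self):
        a = _stream([{"record_id": "a1", "dob": ""}])
        b = _stream([{"record_id": "b1", "dob": ""}])
        assert len(le.make_blocks(a, b, self.SPEC)) == 0

    def test_empty_key_list_rejected(self):
        with pytest.raises(ValueError):
            le.BlockingSpec(keys=())

    def test_union_over_keys_equals_brute_force(self):
        rng = np.random.default_rng(0)
        spec = le.BlockingSpec(
            keys=(
                le.BlockingKey("dob", ("dob",)),
                le.BlockingKey("sx_year", ("surname_sx", "dob_year")),
            )
        )
        def rand_rows(prefix, n):
            return [
                {
                    "record_id": f"{prefix}{i}",
                    "dob": f"200{rng.integers(0,2)}-01-0{rng.integers(1,4)}",
                    "dob_year": f"200{rng.integers(0,2)}",
                    "surname_sx": rng.choice(["S530", "J250", ""]),
                }
                for i in range(n)
            ]
        a, b = _stream(rand_rows("a", 12)), _stream(rand_rows("b", 12))
        got = set(map(tuple, le.make_blocks(a, b, spec).to_numpy()))
        brute = set()
        for ra, rb in itertools.product(a.to_dict("records"), b.to_dict("records")):
            for key in spec.keys:
                vals_a = [ra[f] for f in key.fields]
                vals_b = [rb[f] for f in key.fields]
                if all(v != "" for v in vals_a) and vals_a == vals_b:
                    brute.add((ra["record_id"], rb["record_id"]))
        assert got == brute

    def test_oversized_block_split_by_secondary_key(self):
        spec = le.BlockingSpec(
            keys=(le.BlockingKey("dob", ("dob",), split_field="hospital_code"),),
            max_block_size=4,
        )
        a = _stream(
            [{"record_id": f"a{i}", "dob": "2001-01-01",
              "hospital_code": "H1" if i < 2 else "H2"} for i in range(4)]
        )
        b = _stream(
            [{"record_id": f"b{i}", "dob": "2001-01-01",
              "hospital_code": "H1" if i < 2 else "H2"} for i in range(4)]
        )
        pairs, report = le.make_blocks(a, b, spec, return_report=True)
        # 16 cross pairs exceed the cap; the hospital split keeps within-site pairs
        assert len(pairs) == 8
        assert report["oversized_blocks"]


# ---------------------------------------------------------------------------
# clues

def _pair_frame(a_row, b_row):
    a = _stream([dict(a_row, record_id="a1")])
    b = _stream([dict(b_row, record_id="b1")])
    pairs = pd.DataFrame({"record_id_a": ["a1"], "record_id_b": ["b1"]})
    return le.build_pair_frame(a, b, pairs)


class TestClues:
    CLUES = le.default_clues("infant")

    def test_identical_records_agree_on_all_present_fields(self):
        row = {
            "given": "ROBERT", "given_sx": "R163", "given_ny": "RABAD",
            "surname": "SMITH", "surname_sx": "S530", "surname_ny": "SNAT",
            "dob": "2001-05-05", "dob_year": "2001", "dob_month": "05",
            "dob_day": "05", "sex": "M", "address": "1 HIGH ST", "country": "AUSTRALIA",
            "mrn": "123", "hospital_code": "H1", "event_ord": 100.0,
            "admission_ord": 100.0, "separation_ord": 103.0, "birth_order": 1.0,
        }
        out = le.evaluate_clues(_pair_frame(row, row), self.CLUES)
        present = out.drop(columns=["alias_surname"])  # no aliases on either side
        assert (present.to_numpy() == le.AGREE).all()
        assert out.loc[0, "alias_surname"] == le.MISSING

    def test_blank_names_missing_but_dob_still_evaluated(self):
        a = {"dob": "2001-05-05", "dob_year": "2001", "dob_month": "05", "dob_day": "05"}
        b = {"dob": "2001-05-06", "dob_year": "2001", "dob_month": "05", "dob_day": "06"}
        out = le.evaluate_clues(_pair_frame(a, b), self.CLUES)
        assert out.loc[0, "given_exact"] == le.MISSING
        assert out.loc[0, "surname_soundex"] == le.MISSING
        assert out.loc[0, "dob_exact"] == le.DISAGREE
        assert out.loc[0, "dob_year"] == le.AGREE

    def test_robert_rupert_phonetic_agrees_exact_disagrees(self):
        a = {"given": "ROBERT", "given_sx": "R163", "given_ny": "RABAD"}
        b = {"given": "RUPERT", "given_sx": "R163", "given_ny": "RAPAD"}
        out = le.evaluate_clues(_pair_frame(a, b), self.CLUES)
        assert out.loc[0, "given_exact"] == le.DISAGREE
        assert out.loc[0, "given_soundex"] == le.AGREE

    def test_unknown_field_raises(self):
        with pytest.raises(KeyError):
            le.evaluate_clues(
                _pair_frame({}, {}), (le.Clue("bogus", "exact", "not_a_column"),)
            )

    def test_comparators_symmetric_for_symmetric_fields(self):
        a = {"surname": "SMITH", "surname_sx": "S530", "surname_ny": "SNAT"}
        b = {"surname": "SMYTH", "surname_sx": "S530", "surname_ny": "SNYT"}
        sym = [c for c in self.CLUES if c.kind in ("exact", "alias", "birth_order")]
        out_ab = le.evaluate_clues(_pair_frame(a, b), tuple(sym))
        out_ba = le.evaluate_clues(_pair_frame(b, a), tuple(sym))
        pd.testing.assert_frame_equal(out_ab, out_ba)


# ---------------------------------------------------------------------------
# scoring and classification

class TestScoring:
    def test_zero_weights_score_half(self):
        model = le.MaxentModel(("c1", "c2"), np.zeros(2), np.zeros(2), 0.0)
        assert le.score_pair([le.AGREE, le.DISAGREE], model) == pytest.approx(0.5)

    def test_closed_form(self):
        model = le.MaxentModel(
            ("c1", "c2", "c3"), np.array([2.0, 1.0, 0.5]),
            np.array([-1.5, -0.5, 0.0]), -1.0,
        )
        # outcomes: agree, disagree, missing -> z = 2.0 + (-0.5) + 0 - 1.0
        z = 2.0 - 0.5 - 1.0
        expect = 1 / (1 + np.exp(-z))
        assert le.score_pair([1, -1, 0], model) == pytest.approx(expect, abs=1e-12)

    def test_all_agree_scores_above_all_disagree(self):
        rng = np.random.default_rng(0)
        model = le.MaxentModel(
            tuple("abcd"), np.abs(rng.normal(size=4)), -np.abs(rng.normal(size=4)), 0.1
        )
        hi = le.score_pair([1, 1, 1, 1], model)
        lo = le.score_pair([-1, -1, -1, -1], model)
        assert 0 < lo < hi < 1

    def test_dimension_mismatch_raises(self):
        model = le.MaxentModel(("c1",), np.zeros(1), np.zeros(1), 0.0)
        with pytest.raises(ValueError):
            le.score_pair([1, 1], model)

    def test_separable_toy_set_fit_classifies_perfectly(self):
        rng = np.random.default_rng(1)
        outcomes = pd.DataFrame(
            {"key": rng.choice([1, -1], size=200), "noise": rng.choice([1, -1, 0], size=200)}
        )
        labels = outcomes["key"] == 1
        model = le.fit_maxent_weights(outcomes, labels.to_numpy())
        p = le.score_pairs(outcomes.to_numpy(), model)
        assert ((p >= 0.5) == labels.to_numpy()).all()

    def test_single_class_labels_rejected(self):
        outcomes = pd.DataFrame({"c": [1, 1, -1]})
        with pytest.raises(ValueError):
            le.fit_maxent_weights(outcomes, np.ones(3))

    def test_missing_outcome_never_contributes_disagree_weight(self):
        model = le.MaxentModel(("c1",), np.array([3.0]), np.array([-3.0]), 0.0)
        assert le.score_pair([0], model) == pytest.approx(0.5)


class TestClassify:
    T = le.ThresholdConfig(lower=0.25, upper=0.75)

    @pytest.mark.parametrize(
        "p,expected",
        [(0.80, "match"), (0.50, "review"), (0.10, "non_match"),
         (0.75, "match"), (0.25, "non_match")],
    )
    def test_decision_boundaries(self, p, expected):
        assert le.classify(p, self.T) == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            le.ThresholdConfig(lower=0.8, upper=0.7)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_decisions_partition_all_pairs(self, scores):
        dec = le.classify_scores(np.array(scores), self.T)
        counts = pd.Series(dec).value_counts()
        assert counts.sum() == len(scores)
        assert set(counts.index) <= {"match", "non_match", "review"}


# ---------------------------------------------------------------------------
# threshold tuning

def _brute_force_tune(scores, labels, tm, tf):
    """Exhaustive grid over candidate cut pairs; smallest review band."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    candidates = sorted(set(s) | {0.0, 1.0})
    best = None
    for lo, up in itertools.product(candidates, candidates):
        if not (0 <= lo < up <= 1):
            continue
        missed = 1000 * (y & (s <= lo)).sum() / max(y.sum(), 1)
        acc = s >= up
        fp = 1000 * (acc & ~y).sum() / max(acc.sum(), 1)
        if missed <= tm and fp <= tf:
            band = int(((s > lo) & (s < up)).sum())
            if best is None or band < best:
                best = band
    return best


class TestTuneThresholds:
    def test_separated_scores_collapse_review_band(self):
        scores = np.array([0.1, 0.15, 0.2, 0.9, 0.92, 0.95])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        cfg, report = le.tune_thresholds(scores, labels)
        assert report.feasible
        assert report.review_count == 0
        assert report.missed_per_1000 == 0 and report.false_per_1000 == 0
        assert cfg.lower < cfg.upper

    def test_band_size_matches_brute_force_grid(self):
        rng = np.random.default_rng(2)
        labels = rng.random(120) < 0.5
        scores = np.clip(
            np.where(labels, rng.normal(0.8, 0.15, 120), rng.normal(0.2, 0.15, 120)),
            0.001, 0.999,
        )
        cfg, report = le.tune_thresholds(scores, labels, 5.0, 5.0)
        brute = _brute_force_tune(scores, labels, 5.0, 5.0)
        assert report.feasible
        assert report.review_count == brute

    def test_raising_upper_never_increases_false_positives(self):
        rng = np.random.default_rng(3)
        labels = rng.random(300) < 0.4
        scores = np.clip(rng.random(300) * 0.5 + labels * 0.4, 0, 1)
        fps = []
        for up in [0.5, 0.6, 0.7, 0.8, 0.9]:
            acc = scores >= up
            fps.append((acc & ~labels).sum())
        assert all(a >= b for a, b in zip(fps, fps[1:]))

    def test_targets_validated(self):
        with pytest.raises(ValueError):
            le.tune_thresholds(np.array([0.5]), np.array([True]), -1.0, 2.0)


# ---------------------------------------------------------------------------
# assignment

def _brute_force_greedy_optimum(decisions):
    """Lexicographically greatest matching under the documented tie rules.

    Enumerates every one-to-one subset of the accepted pairs and returns
    the one whose (probability desc, id asc) pick sequence is greatest —
    the exhaustive counterpart of greedy selection.
    """
    cand = [
        (float(p), str(a), str(b))
        for a, b, p in decisions.loc[
            decisions["decision"] == "match", ["record_id_a", "record_id_b", "probability"]
        ].itertuples(index=False)
    ]

    pad = (float("inf"),)
    n = len(cand)

    def sort_key(pairs):
        # inf-padding makes a non-maximal matching compare worse than any
        # matching that extends it, mirroring greedy's run-to-exhaustion
        seq = tuple(
            (-p, a, b) for p, a, b in sorted(pairs, key=lambda t: (-t[0], t[1], t[2]))
        )
        return seq + (pad,) * (n - len(seq))

    best = None
    for r in range(n + 1):
        for combo in itertools.combinations(cand, r):
            ids_a = [a for _, a, _ in combo]
            ids_b = [b for _, _, b in combo]
            if len(set(ids_a)) != len(ids_a) or len(set(ids_b)) != len(ids_b):
                continue
            key = sort_key(combo)
            if best is None or key < best[0]:
                best = (key, combo)
    return {(a, b) for _, a, b in best[1]} if best else set()


class TestResolveAssignments:
    def test_higher_probability_wins_shared_record(self):
        dec = pd.DataFrame(
            {
                "record_id_a": ["a1", "a1"],
                "record_id_b": ["b1", "b2"],
                "probability": [0.9, 0.8],
                "decision": ["match", "match"],
            }
        )
        links = le.resolve_assignments(dec)
        assert set(zip(links.record_id_a, links.record_id_b)) == {("a1", "b1")}

    def test_empty_decisions_empty_map(self):
        assert len(le.resolve_assignments(pd.DataFrame(columns=["decision"]))) == 0

    def test_matches_exhaustive_optimum_under_tie_rules(self):
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(14):
            rows.append(
                (f"a{rng.integers(0, 5)}", f"b{rng.integers(0, 5)}", round(float(rng.random()), 3))
            )
        dec = pd.DataFrame(rows, columns=["record_id_a", "record_id_b", "probability"])
        dec = dec.drop_duplicates(["record_id_a", "record_id_b"])
        dec["decision"] = "match"
        links = le.resolve_assignments(dec)
        got = set(zip(links.record_id_a, links.record_id_b))
        assert got == _brute_force_greedy_optimum(dec)

    def test_oracle_policy_confirms_true_review_pairs(self):
        dec = pd.DataFrame(
            {
                "record_id_a": ["a1", "a2"],
                "record_id_b": ["b1", "b2"],
                "probability": [0.5, 0.5],
                "decision": ["review", "review"],
            }
        )
        links = le.resolve_assignments(
            dec, review_policy="oracle", truth_pairs={("a1", "b1")}
        )
        assert set(zip(links.record_id_a, links.record_id_b)) == {("a1", "b1")}
        assert len(le.resolve_assignments(dec, review_policy="reject")) == 0


# ---------------------------------------------------------------------------
# parameter recovery and pipeline equivalence

def test_maxent_weight_recovery_small():
    """Known-weight simulation at moderate n recovers weights closely."""
    rng = np.random.default_rng(7)
    names = ("c1", "c2", "c3")
    aw = np.array([1.5, 0.8, -0.4])
    dw = np.array([-1.2, -0.6, 0.3])
    n = 20_000
    outcomes = rng.choice([1, -1, 0], size=(n, 3))
    truth = le.MaxentModel(names, aw, dw, -0.3)
    p = le.score_pairs(outcomes, truth)
    y = rng.random(n) < p
    fitted = le.fit_maxent_weights(pd.DataFrame(outcomes, columns=names), y)
    assert np.abs(fitted.agree_weights - aw).max() < 0.15
    assert np.abs(fitted.disagree_weights - dw).max() < 0.15


def test_blocking_plus_scoring_equals_all_pairs_on_small_streams():
    """Candidate restriction loses no above-threshold match on <=200 records."""
    params = zero_error_params(n=150, seed=3)
    errors = ErrorModel(
        typo_rate=0.05, name_missing_rate_public=0.0, name_missing_rate_private=0.0,
        dob_digit_swap_rate=0.0, alias_rate=0.0, address_change_rate=0.0,
    )
    births, maternal, _, truth = generate_cohort(params, errors)
    models, thresholds = pipeline.fit_on_training_cohort(
        zero_error_params(n=400, seed=9), errors
    )
    model, cfg = models["mother"], thresholds["mother"]
    a, b = pipeline._streams_for_role(births, maternal, "mother")
    clues = le.default_clues("mother")
    clue_cols = [c.name for c in clues]

    blocked = pipeline._score_candidates(a, b, "mother", model, le.DEFAULT_BLOCKING)
    blocked_matches = set(
        zip(
            blocked.loc[blocked["probability"] >= cfg.upper, "record_id_a"],
            blocked.loc[blocked["probability"] >= cfg.upper, "record_id_b"],
        )
    )

    all_pairs = a.merge(b, how="cross", suffixes=("_a", "_b")).rename(
        columns={"record_id_a": "record_id_a", "record_id_b": "record_id_b"}
    )
    outcomes = le.evaluate_clues(all_pairs, clues)
    p = le.score_pairs(outcomes.to_numpy(), model)
    full_matches = set(
        zip(all_pairs.loc[p >= cfg.upper, "record_id_a"], all_pairs.loc[p >= cfg.upper, "record_id_b"])
    )
    assert blocked_matches == full_matches


def test_blocking_captures_every_true_pair_on_error_free_data(zero_cohort):
    births, maternal, infant, truth = zero_cohort
    a, b = pipeline._streams_for_role(births, maternal, "mother")
    pairs = le.make_blocks(a, b)
    captured = set(zip(pairs.record_id_a, pairs.record_id_b))
    want = set(zip(truth.mother_pairs["delivery_id"], truth.mother_pairs["hosp_record_id"]))
    assert want <= captured
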