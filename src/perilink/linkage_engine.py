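"""Blocked, clue-based probabilistic linkage with dual decision thresholds.

The machinery follows the two-stage design used by health record-linkage
units: *blocking* first restricts candidate pairs to records sharing a
derived key (date of birth; surname phonetic code plus birth year; MRN plus
hospital), then each candidate pair is *scored*. Scoring evaluates a set of
"clues" — field comparators returning agree / disagree / missing — and
combines them through a maximum-entropy model (its dual, an L2-regularized
binary logistic model) into a match probability in (0, 1). Dual probability
cut-offs (defaults 0.25 and 0.75) classify pairs as non-matches, matches,
or possible matches for clerical review; the cut-offs can be tuned against
labelled data to hit target missed-link and false-positive rates. A greedy
one-to-one assignment resolves competing matches.

Missing clue outcomes are the zero-contribution reference level: a blank
name neither supports nor contradicts a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .identifier_prep import EMPTY_CODE, normalize_address, normalize_name, nysiis, soundex

__all__ = [
    "ThresholdConfig",
    "BlockingKey",
    "BlockingSpec",
    "Clue",
    "MaxentModel",
    "TuningReport",
    "DEFAULT_BLOCKING",
    "default_clues",
    "standardize_stream",
    "make_blocks",
    "build_pair_frame",
    "evaluate_clues",
    "outcomes_to_features",
    "fit_maxent_weights",
    "score_pairs",
    "score_pair",
    "classify",
    "classify_scores",
    "tune_thresholds",
    "resolve_assignments",
]

AGREE, DISAGREE, MISSING = 1, -1, 0


@dataclass(frozen=True)
class ThresholdConfig:
    """Lower/upper probability cut-offs; the open interval is the review band."""

    lower: float = 0.25
    upper: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValueError(
                f"require 0 <= lower < upper <= 1, got ({self.lower}, {self.upper})"
            )


@dataclass(frozen=True)
class BlockingKey:
    name: str
    fields: tuple[str, ...]
    # secondary field used to split blocks whose pair count exceeds the cap
    split_field: str | None = None


@dataclass(frozen=True)
class BlockingSpec:
    keys: tuple[BlockingKey, ...]
    max_block_size: int = 1000

    def __post_init__(self) -> None:
        if not self.keys:
            raise ValueError("BlockingSpec requires at least one key")
        if self.max_block_size < 2:
            raise ValueError("max_block_size must be >= 2")


DEFAULT_BLOCKING = BlockingSpec(
    keys=(
        BlockingKey("dob", ("dob",), split_field="hospital_code"),
        BlockingKey("surname_sx_year", ("surname_sx", "dob_year"), split_field="hospital_code"),
        BlockingKey("mrn_hospital", ("mrn", "hospital_code")),
    )
)


# ---------------------------------------------------------------------------
# standardization of a record stream into comparator columns

_PHONETIC_CACHE: dict[str, tuple[str, str]] = {}


def _phonetics(values: pd.Series) -> tuple[pd.Series, pd.Series]:
    sx, ny = {}, {}
    for v in values.unique():
        cached = _PHONETIC_CACHE.get(v)
        if cached is None:
            cached = (soundex(v), nysiis(v))
            _PHONETIC_CACHE[v] = cached
        sx[v], ny[v] = cached
    return values.map(sx), values.map(ny)


_ROLE_FIELDS = {
    # role -> mapping of standardized column -> source column
    "mother_birth": {
        "given": "given_name", "surname": "surname", "alias": "alias",
        "dob": "dob", "sex": "sex", "address": "address",
        "country": "country_of_birth", "mrn": "mrn",
        "hospital_code": "hospital_code", "event_date": "i_dob",
        "birth_order": None, "plurality": "plurality",
    },
    "infant_birth": {
        "given": "i_given_name", "surname": "i_surname", "alias": None,
        "dob": "i_dob", "sex": "i_sex", "address": "address",
        "country": None, "mrn": "i_mrn",
        "hospital_code": "hospital_code", "event_date": "i_dob",
        "birth_order": "birth_order", "plurality": "plurality",
    },
    "hospital": {
        "given": "given_name", "surname": "surname", "alias": "alias",
        "dob": "dob", "sex": "sex", "address": "address",
        "country": "country_of_birth", "mrn": "mrn",
        "hospital_code": "hospital_code", "event_date": None,
        "birth_order": "birth_order", "plurality": "plurality",
    },
}


def standardize_stream(df: pd.DataFrame, role: str, id_col: str) -> pd.DataFrame:
    """Project a record stream onto the standardized comparator columns.

    *role* selects the field mapping: ``mother_birth`` (maternal identifiers
    of a birth-registration stream), ``infant_birth`` (infant identifiers of
    the same stream) or ``hospital``. The result carries normalized names,
    phonetic codes, date components, and — for hospital records — the
    admission interval as day ordinals.
    """
    if role not in _ROLE_FIELDS:
        raise ValueError(f"unknown role {role!r}")
    m = _ROLE_FIELDS[role]
    out = pd.DataFrame(index=df.index)
    out["record_id"] = df[id_col].astype(str)

    def src(key: str, default="") -> pd.Series:
        col = m[key]
        if col is None or col not in df.columns:
            return pd.Series(default, index=df.index)
        return df[col]

    for key, norm in (("given", normalize_name), ("surname", normalize_name),
                      ("alias", normalize_name)):
        vals = src(key).fillna("").astype(str)
        uniq = {v: norm(v) for v in vals.unique()}
        out[key] = vals.map(uniq)
    out["given_sx"], out["given_ny"] = _phonetics(out["given"])
    out["surname_sx"], out["surname_ny"] = _phonetics(out["surname"])

    dob = src("dob").fillna("").astype(str).str.strip()
    out["dob"] = dob
    parts = dob.str.extract(r"^(\d{4})-(\d{2})-(\d{2})$")
    out["dob_year"], out["dob_month"], out["dob_day"] = parts[0].fillna(""), parts[1].fillna(""), parts[2].fillna("")

    sex = src("sex").fillna("").astype(str).str.strip().str.upper()
    out["sex"] = sex.where(sex.isin(["M", "F"]), "")

    addr = src("address").fillna("").astype(str)
    uniq = {v: normalize_address(v) for v in addr.unique()}
    out["address"] = addr.map(uniq)
    country = src("country").fillna("").astype(str)
    out["country"] = country.map({v: normalize_name(v) for v in country.unique()})
    out["mrn"] = src("mrn").fillna("").astype(str).str.strip().str.upper()
    out["hospital_code"] = src("hospital_code").fillna("").astype(str).str.strip().str.upper()

    event = pd.to_datetime(src("event_date", None), errors="coerce")
    out["event_ord"] = event.map(lambda t: t.toordinal() if pd.notna(t) else np.nan)
    for col in ("admission_date", "separation_date"):
        if col in df.columns:
            d = pd.to_datetime(df[col], errors="coerce")
            out[col.replace("_date", "_ord")] = d.map(
                lambda t: t.toordinal() if pd.notna(t) else np.nan
            )
        else:
            out[col.replace("_date", "_ord")] = np.nan

    bo = pd.to_numeric(src("birth_order", np.nan), errors="coerce")
    out["birth_order"] = bo.where(bo > 0)
    plur = pd.to_numeric(src("plurality", 1), errors="coerce").fillna(1)
    out["stratum"] = np.where(plur > 1, "multiple", "singleton")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# blocking

def make_blocks(
    stream_a: pd.DataFrame,
    stream_b: pd.DataFrame,
    spec: BlockingSpec = DEFAULT_BLOCKING,
    *,
    return_report: bool = False,
):
    """Candidate pairs: union over keys of within-key cross pairs.

    Records with a missing component of a key do not enter that key's
    blocks. A block whose pair count would exceed ``max_block_size`` is
    split by the key's secondary field; a block still oversized after the
    split is kept and flagged in the report rather than silently dropped.
    Returns a two-column frame ``(id_a, id_b)`` with no duplicate pairs.
    """
    pieces: list[pd.DataFrame] = []
    oversized: list[tuple[str, int]] = []

    def key_pairs(a: pd.DataFrame, b: pd.DataFrame, fields: tuple[str, ...]) -> pd.DataFrame:
        a = a[["record_id", *fields]].copy()
        b = b[["record_id", *fields]].copy()
        for f in fields:
            a = a[a[f].astype(str) != ""]
            b = b[b[f].astype(str) != ""]
        merged = a.merge(b, on=list(fields), suffixes=("_a", "_b"))
        return merged[["record_id_a", "record_id_b"]]

    for key in spec.keys:
        fields = key.fields
        a_cnt = stream_a.groupby(list(fields), dropna=False).size()
        b_cnt = stream_b.groupby(list(fields), dropna=False).size()
        sizes = (a_cnt * b_cnt).dropna()
        big = sizes[sizes > spec.max_block_size]
        if len(big) and key.split_field:
            big_vals = set(big.index)
            keyvals_a = list(zip(*(stream_a[f] for f in fields))) if len(fields) > 1 else stream_a[fields[0]]
            keyvals_b = list(zip(*(stream_b[f] for f in fields))) if len(fields) > 1 else stream_b[fields[0]]
            in_big_a = pd.Series(keyvals_a, index=stream_a.index).isin(big_vals)
            in_big_b = pd.Series(keyvals_b, index=stream_b.index).isin(big_vals)
            pieces.append(key_pairs(stream_a[~in_big_a], stream_b[~in_big_b], fields))
            pieces.append(
                key_pairs(stream_a[in_big_a], stream_b[in_big_b], fields + (key.split_field,))
            )
            oversized.extend((f"{key.name}:{v}", int(s)) for v, s in big.items())
        else:
            pieces.append(key_pairs(stream_a, stream_b, fields))
            if len(big):
                oversized.extend((f"{key.name}:{v} (unsplit)", int(s)) for v, s in big.items())

    pairs = (
        pd.concat(pieces, ignore_index=True).drop_duplicates().reset_index(drop=True)
        if pieces
        else pd.DataFrame(columns=["record_id_a", "record_id_b"])
    )
    if return_report:
        return pairs, {"n_pairs": len(pairs), "oversized_blocks": oversized}
    return pairs


# ---------------------------------------------------------------------------
# clues

@dataclass(frozen=True)
class Clue:
    """A named pairwise field comparator with a comparison kind."""

    name: str
    kind: str  # exact | date_component | window | alias | birth_order
    column: str = ""


def default_clues(role: str) -> tuple[Clue, ...]:
    """Default clue set for a linkage role (``mother`` or ``infant``).

    Mirrors the fields record-linkage units match on: names exact and
    phonetic, date of birth in full and by component, sex, address,
    country of birth, hospital + MRN, alias names, the admission-date/
    birth-date consistency window, and birth order for multiples.
    """
    clues = [
        Clue("given_exact", "exact", "given"),
        Clue("given_soundex", "exact", "given_sx"),
        Clue("given_nysiis", "exact", "given_ny"),
        Clue("surname_exact", "exact", "surname"),
        Clue("surname_soundex", "exact", "surname_sx"),
        Clue("surname_nysiis", "exact", "surname_ny"),
        Clue("alias_surname", "alias"),
        Clue("dob_exact", "exact", "dob"),
        Clue("dob_year", "exact", "dob_year"),
        Clue("dob_month", "exact", "dob_month"),
        Clue("dob_day", "exact", "dob_day"),
        Clue("sex", "exact", "sex"),
        Clue("address", "exact", "address"),
        Clue("country", "exact", "country"),
        Clue("mrn", "exact", "mrn"),
        Clue("hospital", "exact", "hospital_code"),
        Clue(f"admission_window_{role}", "window", role),
    ]
    if role == "infant":
        clues.append(Clue("birth_order", "birth_order"))
    return tuple(clues)


def build_pair_frame(
    stream_a: pd.DataFrame, stream_b: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Join standardized columns of both records onto each candidate pair."""
    a = stream_a.add_suffix("_a").rename(columns={"record_id_a": "record_id_a"})
    b = stream_b.add_suffix("_b")
    out = pairs.merge(a, on="record_id_a", how="left").merge(b, on="record_id_b", how="left")
    return out


def _exact_outcome(pf: pd.DataFrame, column: str) -> np.ndarray:
    a = pf[f"{column}_a"].fillna("").astype(str).to_numpy()
    b = pf[f"{column}_b"].fillna("").astype(str).to_numpy()
    present = (a != "") & (b != "") & (a != EMPTY_CODE) & (b != EMPTY_CODE)
    return np.where(present, np.where(a == b, AGREE, DISAGREE), MISSING).astype(np.int8)


def evaluate_clues(pair_frame: pd.DataFrame, clues: tuple[Clue, ...]) -> pd.DataFrame:
    """Outcome vector per candidate pair: one agree/disagree/missing per clue.

    Deterministic; a field missing on either record yields the missing
    outcome for every clue that reads it.
    """
    out = {}
    for clue in clues:
        if clue.kind == "exact":
            col = clue.column
            if f"{col}_a" not in pair_frame.columns or f"{col}_b" not in pair_frame.columns:
                raise KeyError(f"clue {clue.name!r} references unknown field {col!r}")
            out[clue.name] = _exact_outcome(pair_frame, col)
        elif clue.kind == "alias":
            sa = pair_frame["surname_a"].fillna("").to_numpy()
            sb = pair_frame["surname_b"].fillna("").to_numpy()
            aa = pair_frame["alias_a"].fillna("").to_numpy()
            ab = pair_frame["alias_b"].fillna("").to_numpy()
            any_alias = (aa != "") | (ab != "")
            cross = ((aa != "") & (aa == sb)) | ((ab != "") & (ab == sa)) | (
                (aa != "") & (aa == ab)
            )
            out[clue.name] = np.where(
                any_alias, np.where(cross, AGREE, DISAGREE), MISSING
            ).astype(np.int8)
        elif clue.kind == "window":
            event = pair_frame["event_ord_a"].to_numpy(dtype=float)
            adm = pair_frame["admission_ord_b"].to_numpy(dtype=float)
            if clue.column == "infant":
                ok = np.abs(adm - event) <= 1
                present = ~np.isnan(adm - event)
            else:
                sep = pair_frame["separation_ord_b"].to_numpy(dtype=float)
                ok = (adm <= event) & (event <= sep)
                present = ~np.isnan(adm + event + sep)
            out[clue.name] = np.where(
                present, np.where(ok, AGREE, DISAGREE), MISSING
            ).astype(np.int8)
        elif clue.kind == "birth_order":
            a = pair_frame["birth_order_a"].to_numpy(dtype=float)
            b = pair_frame["birth_order_b"].to_numpy(dtype=float)
            present = ~np.isnan(a) & ~np.isnan(b)
            out[clue.name] = np.where(
                present, np.where(a == b, AGREE, DISAGREE), MISSING
            ).astype(np.int8)
        else:
            raise ValueError(f"unknown clue kind {clue.kind!r}")
    return pd.DataFrame(out, index=pair_frame.index)


# ---------------------------------------------------------------------------
# maximum-entropy scoring

@dataclass(frozen=True)
class MaxentModel:
    """Fitted clue weights: one agree and one disagree weight per clue."""

    clue_names: tuple[str, ...]
    agree_weights: np.ndarray
    disagree_weights: np.ndarray
    intercept: float

    def weight_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clue": self.clue_names,
                "agree_weight": self.agree_weights,
                "disagree_weight": self.disagree_weights,
            }
        )


def outcomes_to_features(outcomes: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Encode ternary outcomes as paired agree/disagree indicator columns.

    Missing is the reference level (both indicators zero), so a missing
    field can never contribute the disagree weight.
    """
    arr = np.asarray(outcomes, dtype=np.int8)
    return np.concatenate([(arr == AGREE), (arr == DISAGREE)], axis=1).astype(np.float64)


def fit_maxent_weights(
    outcomes: pd.DataFrame,
    labels: np.ndarray,
    *,
    l2: float = 1e-4,
    tol: float = 1e-8,
) -> MaxentModel:
    """Fit clue weights by regularized maximum likelihood.

    The maximum-entropy pair-classification model with indicator features
    is fit in its dual, binary logistic, form; a small absolute L2 penalty
    (strength ``l2``) keeps the optimum unique and the fit reproducible
    while vanishing relative to the likelihood at scale. Labels must
    contain both classes.
    """
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels must contain both matches and non-matches")
    X = outcomes_to_features(outcomes)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    clf = LogisticRegression(C=1.0 / l2, tol=tol, solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    k = outcomes.shape[1]
    names = tuple(outcomes.columns) if hasattr(outcomes, "columns") else tuple(
        f"clue_{i}" for i in range(k)
    )
    coef = clf.coef_.ravel()
    return MaxentModel(
        clue_names=names,
        agree_weights=coef[:k].copy(),
        disagree_weights=coef[k:].copy(),
        intercept=float(clf.intercept_[0]),
    )


def score_pairs(outcomes: pd.DataFrame | np.ndarray, model: MaxentModel) -> np.ndarray:
    """Match probability per pair under the fitted weights."""
    arr = np.asarray(outcomes, dtype=np.int8)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != len(model.clue_names):
        raise ValueError(
            f"outcome vector has {arr.shape[1]} clues, model expects {len(model.clue_names)}"
        )
    z = (
        (arr == AGREE) @ model.agree_weights
        + (arr == DISAGREE) @ model.disagree_weights
        + model.intercept
    )
    return 1.0 / (1.0 + np.exp(-z))


def score_pair(outcome_vector, model: MaxentModel) -> float:
    """Probability that a single candidate pair is a match."""
    return float(score_pairs(np.asarray(outcome_vector), model)[0])


def classify(probability: float, thresholds: ThresholdConfig) -> str:
    """``match`` if p >= upper, ``non_match`` if p <= lower, else ``review``."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability out of [0,1]: {probability}")
    if probability >= thresholds.upper:
        return "match"
    if probability <= thresholds.lower:
        return "non_match"
    return "review"


def classify_scores(scores: np.ndarray, thresholds: ThresholdConfig) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("probabilities out of [0,1]")
    return np.select(
        [scores >= thresholds.upper, scores <= thresholds.lower],
        ["match", "non_match"],
        "review",
    )


# ---------------------------------------------------------------------------
# threshold tuning

@dataclass(frozen=True)
class TuningReport:
    feasible: bool
    missed_per_1000: float
    false_per_1000: float
    review_count: int


def tune_thresholds(
    scores: np.ndarray,
    labels: np.ndarray,
    target_missed_per_1000: float = 1.0,
    target_false_per_1000: float = 2.0,
) -> tuple[ThresholdConfig, TuningReport]:
    """Grid-search cut-offs meeting both quality targets with the smallest
    clerical-review band.

    Missed links are true pairs auto-rejected (p <= lower) per 1,000 true
    pairs; false positives are non-pairs auto-accepted (p >= upper) per
    1,000 auto-accepted pairs. Because the missed rate depends only on the
    lower cut and the false-positive rate only on the upper cut, the band
    is minimized by the largest feasible lower and the smallest feasible
    upper; perfectly separated scores collapse the band to empty. If no
    cut satisfies a target the extreme cut is kept and the report is
    flagged infeasible.
    """
    for t in (target_missed_per_1000, target_false_per_1000):
        if not 0.0 <= t <= 1000.0:
            raise ValueError("targets must be in [0, 1000]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.size == 0:
        raise ValueError("no scored pairs")
    n_true = int(y.sum())
    order = np.argsort(s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]

    # lower candidates: cut at each unique score value (p <= lower rejected)
    uniq, last_idx = np.unique(s_sorted, return_index=True)
    counts = np.diff(np.append(last_idx, s_sorted.size))
    true_cum = np.cumsum(np.where(y_sorted, 1, 0))
    # true pairs with score <= uniq[i]
    true_le = true_cum[last_idx + counts - 1]
    missed_rate = 1000.0 * true_le / max(n_true, 1)
    feasible_lower = uniq[missed_rate <= target_missed_per_1000]
    # lower = 0 rejects nothing and is always admissible as a fallback
    lower = float(feasible_lower.max()) if feasible_lower.size else 0.0

    # upper candidates: accept p >= u
    false_cum = np.cumsum(np.where(~y_sorted[::-1], 1, 0))[::-1]
    total_ge = np.arange(s_sorted.size, 0, -1)
    false_ge = false_cum[last_idx]
    n_ge = total_ge[last_idx]
    fp_rate = np.where(n_ge > 0, 1000.0 * false_ge / np.maximum(n_ge, 1), 0.0)
    ok = fp_rate <= target_false_per_1000
    upper = float(uniq[ok].min()) if ok.any() else 1.0

    upper = min(max(upper, 1e-9), 1.0)
    if lower >= upper:  # separated: collapse toward a single cut
        lower = np.nextafter(upper, 0.0)
    lower = max(lower, 0.0)

    cfg = ThresholdConfig(lower=lower, upper=upper)
    auto_match = s >= cfg.upper
    auto_reject = s <= cfg.lower
    n_match = int(auto_match.sum())
    achieved_fp = 1000.0 * float((auto_match & ~y).sum()) / max(n_match, 1)
    achieved_missed = 1000.0 * float((auto_reject & y).sum()) / max(n_true, 1)
    report = TuningReport(
        feasible=bool(
            achieved_missed <= target_missed_per_1000
            and achieved_fp <= target_false_per_1000
        ),
        missed_per_1000=achieved_missed,
        false_per_1000=achieved_fp,
        review_count=int((~auto_match & ~auto_reject).sum()),
    )
    return cfg, report


# ---------------------------------------------------------------------------
# one-to-one assignment

def resolve_assignments(
    decisions: pd.DataFrame,
    *,
    review_policy: str = "reject",
    truth_pairs: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Greedy descending-probability one-to-one link map.

    Accepted pairs are the auto-matches plus, under the ``oracle`` review
    policy (synthetic data only), review-band pairs confirmed by ground
    truth; under ``reject`` the review band is dropped. Ties in probability
    break by stable (record_id_a, record_id_b) order.
    """
    if review_policy not in ("reject", "oracle"):
        raise ValueError(f"unknown review policy {review_policy!r}")
    if decisions.empty:
        return pd.DataFrame(columns=["record_id_a", "record_id_b", "probability"])
    acc = decisions["decision"] == "match"
    if review_policy == "oracle":
        if truth_pairs is None:
            raise ValueError("oracle review policy requires truth_pairs")
        rev = decisions["decision"] == "review"
        if rev.any():
            keys = list(zip(decisions["record_id_a"], decisions["record_id_b"]))
            confirmed = pd.Series([k in truth_pairs for k in keys], index=decisions.index)
            acc = acc | (rev & confirmed)
    cand = decisions.loc[acc, ["record_id_a", "record_id_b", "probability"]]
    cand = cand.sort_values(
        ["probability", "record_id_a", "record_id_b"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    used_a: set = set()
    used_b: set = set()
    rows = []
    for ra, rb, p in cand.itertuples(index=False):
        if ra in used_a or rb in used_b:
            continue
        used_a.add(ra)
        used_b.add(rb)
        rows.append((ra, rb, p))
    return pd.DataFrame(rows, columns=["record_id_a", "record_id_b", "probability"])
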