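"""End-to-end orchestration: generate → standardize → link → group → report.

The two linkages are run separately: mothers (one record per delivery on
the registration side, since multiple births carry identical maternal
identifiers) against maternal delivery admissions, and infants (one record
per birth) against infant birth admissions. Within each linkage, singleton
and multiple pregnancies are linked in separate passes and never compete
for the same assignment.

Clue weights are fitted on a held-out labelled cohort (a second synthetic
draw) and the dual thresholds tuned there against the target quality
rates, then applied unchanged to the study cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import linkage_engine as le
from .group_assignment import assign_groups, stratify
from .reporting_eval import QualityReport, evaluate_quality
from .synthetic_cohort import CohortParams, ErrorModel, GroundTruth, generate_cohort

__all__ = ["LinkageRun", "link_stream", "fit_on_training_cohort", "run_study"]


@dataclass
class LinkageRun:
    """Everything produced by one synthetic end-to-end run."""

    births: pd.DataFrame
    maternal_hospital: pd.DataFrame
    infant_hospital: pd.DataFrame
    truth: GroundTruth
    mother_links: pd.DataFrame
    infant_links: pd.DataFrame
    groups: dict[str, pd.DataFrame]
    stratified: pd.DataFrame
    quality: QualityReport
    mother_model: le.MaxentModel
    infant_model: le.MaxentModel
    thresholds: dict[str, le.ThresholdConfig]


def _streams_for_role(
    births: pd.DataFrame, hospital: pd.DataFrame, role: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if role == "mother":
        a_src = births.drop_duplicates("delivery_id")
        a = le.standardize_stream(a_src, "mother_birth", "delivery_id")
    elif role == "infant":
        a = le.standardize_stream(births, "infant_birth", "birth_record_id")
    else:
        raise ValueError(f"unknown role {role!r}")
    b = le.standardize_stream(hospital, "hospital", "hosp_record_id")
    return a, b


def _score_candidates(
    a: pd.DataFrame,
    b: pd.DataFrame,
    role: str,
    model: le.MaxentModel | None,
    blocking: le.BlockingSpec,
) -> pd.DataFrame:
    """Blocked candidate pairs with clue outcomes (and scores if a model)."""
    clues = le.default_clues(role)
    parts = []
    for stratum in ("singleton", "multiple"):
        sa = a[a["stratum"] == stratum]
        sb = b[b["stratum"] == stratum]
        if sa.empty or sb.empty:
            continue
        pairs = le.make_blocks(sa, sb, blocking)
        if pairs.empty:
            continue
        pf = le.build_pair_frame(sa, sb, pairs)
        outcomes = le.evaluate_clues(pf, clues)
        out = pairs.copy()
        out["stratum"] = stratum
        for c in outcomes.columns:
            out[c] = outcomes[c].to_numpy()
        parts.append(out)
    if not parts:
        cols = ["record_id_a", "record_id_b", "stratum"] + [c.name for c in clues]
        return pd.DataFrame(columns=cols)
    cand = pd.concat(parts, ignore_index=True)
    if model is not None:
        clue_cols = [c.name for c in clues]
        cand["probability"] = le.score_pairs(cand[clue_cols].to_numpy(), model)
    return cand


def link_stream(
    births: pd.DataFrame,
    hospital: pd.DataFrame,
    role: str,
    model: le.MaxentModel,
    thresholds: le.ThresholdConfig,
    *,
    blocking: le.BlockingSpec = le.DEFAULT_BLOCKING,
    review_policy: str = "reject",
    truth_pairs: set[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one full linkage (blocking, scoring, classification, assignment).

    Returns ``(links, decisions)``: the one-to-one link map and the full
    scored decision table. Assignment is resolved per stratum so singleton
    and multiple pregnancies never compete.
    """
    a, b = _streams_for_role(births, hospital, role)
    cand = _score_candidates(a, b, role, model, blocking)
    if cand.empty:
        empty = pd.DataFrame(columns=["record_id_a", "record_id_b", "probability"])
        return empty, cand
    cand["decision"] = le.classify_scores(cand["probability"].to_numpy(), thresholds)
    links = []
    for _, sub in cand.groupby("stratum"):
        links.append(
            le.resolve_assignments(
                sub, review_policy=review_policy, truth_pairs=truth_pairs
            )
        )
    links_df = pd.concat(links, ignore_index=True) if links else pd.DataFrame(
        columns=["record_id_a", "record_id_b", "probability"]
    )
    return links_df, cand


def _truth_sets(truth: GroundTruth) -> dict[str, set[tuple[str, str]]]:
    return {
        "mother": set(
            zip(truth.mother_pairs["delivery_id"], truth.mother_pairs["hosp_record_id"])
        ),
        "infant": set(
            zip(truth.infant_pairs["birth_record_id"], truth.infant_pairs["hosp_record_id"])
        ),
    }


def fit_on_training_cohort(
    params: CohortParams,
    errors: ErrorModel,
    *,
    blocking: le.BlockingSpec = le.DEFAULT_BLOCKING,
    target_missed_per_1000: float = 1.0,
    target_false_per_1000: float = 2.0,
) -> tuple[dict[str, le.MaxentModel], dict[str, le.ThresholdConfig]]:
    """Fit clue weights and tune thresholds on a labelled training cohort."""
    births, maternal, infant, truth = generate_cohort(params, errors)
    tsets = _truth_sets(truth)
    models: dict[str, le.MaxentModel] = {}
    thresholds: dict[str, le.ThresholdConfig] = {}
    for role, hosp in (("mother", maternal), ("infant", infant)):
        a, b = _streams_for_role(births, hosp, role)
        cand = _score_candidates(a, b, role, None, blocking)
        clue_cols = [c.name for c in le.default_clues(role)]
        keys = list(zip(cand["record_id_a"], cand["record_id_b"]))
        labels = np.fromiter((k in tsets[role] for k in keys), bool, len(keys))
        model = le.fit_maxent_weights(cand[clue_cols], labels)
        scores = le.score_pairs(cand[clue_cols].to_numpy(), model)
        cfg, _report = le.tune_thresholds(
            scores, labels, target_missed_per_1000, target_false_per_1000
        )
        models[role] = model
        thresholds[role] = cfg
    return models, thresholds


def run_study(
    params: CohortParams,
    errors: ErrorModel | None = None,
    *,
    train_deliveries: int = 2000,
    review_policy: str = "oracle",
    blocking: le.BlockingSpec = le.DEFAULT_BLOCKING,
) -> LinkageRun:
    """Full synthetic study: train, link both streams, group, evaluate.

    The training cohort is an independent draw (seed offset by a large
    constant) of ``train_deliveries`` deliveries under the same error
    model. The review band is resolved by the ground-truth oracle by
    default, emulating clerical review on synthetic data; pass
    ``review_policy="reject"`` for a blind run.
    """
    errors = ErrorModel() if errors is None else errors
    train_params = replace(
        params, n_deliveries=train_deliveries, seed=(params.seed + 990_001) % 2**31
    )
    models, thresholds = fit_on_training_cohort(train_params, errors, blocking=blocking)

    births, maternal, infant, truth = generate_cohort(params, errors)
    tsets = _truth_sets(truth)
    mother_links, _ = link_stream(
        births, maternal, "mother", models["mother"], thresholds["mother"],
        blocking=blocking, review_policy=review_policy, truth_pairs=tsets["mother"],
    )
    infant_links, _ = link_stream(
        births, infant, "infant", models["infant"], thresholds["infant"],
        blocking=blocking, review_policy=review_policy, truth_pairs=tsets["infant"],
    )

    groups = assign_groups(
        births,
        mother_links.rename(columns={"record_id_a": "delivery_id"}),
        infant_links.rename(columns={"record_id_a": "birth_record_id"}),
        maternal_admissions=maternal,
        infant_admissions=infant,
    )
    stratified = stratify(groups["births"])

    declared = set(zip(mother_links["record_id_a"], mother_links["record_id_b"])) | set(
        zip(infant_links["record_id_a"], infant_links["record_id_b"])
    )
    quality = evaluate_quality(declared, tsets["mother"] | tsets["infant"])

    return LinkageRun(
        births=births,
        maternal_hospital=maternal,
        infant_hospital=infant,
        truth=truth,
        mother_links=mother_links,
        infant_links=infant_links,
        groups=groups,
        stratified=stratified,
        quality=quality,
        mother_model=models["mother"],
        infant_model=models["infant"],
        thresholds=thresholds,
    )
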