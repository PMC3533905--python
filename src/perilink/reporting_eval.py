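"""Linkage-rate tables, stratified rates, characteristic comparisons, and
ground-truth quality metrics.

Percentages are printed to one decimal, rounded half-up, and always
recompute from their own count and column total. Quality is reported in the
units linkage units quote: missed links per 1,000 true record pairs, and
false positive links per 1,000 declared links, with exact integer
arithmetic before the rate conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .group_assignment import BIRTH_GROUPS

__all__ = [
    "pct",
    "QualityReport",
    "linkage_rate_table",
    "rate_by_stratum",
    "identification_coverage",
    "characteristics_table",
    "evaluate_quality",
]

log = logging.getLogger(__name__)


def pct(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of *count* in *total*, rounded half-up to *decimals*."""
    if total == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(count) * 100 / Decimal(total)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def _cell(count: int, total: int) -> str:
    return f"{count} ({pct(count, total)})"


def linkage_rate_table(stratified: pd.DataFrame) -> pd.DataFrame:
    """Counts and one-decimal percentages of each linkage group by stratum.

    Rows are the four birth-record groups plus a total row; columns are the
    populated strata plus ``total``. Each percentage is of the column N, so
    group percentages in a column sum to ~100.
    """
    if stratified.empty:
        raise ValueError("empty group table")
    strata = [s for s in sorted(stratified["stratum"].unique())]
    cols = strata + ["total"]
    table = pd.DataFrame(index=list(BIRTH_GROUPS) + ["N"], columns=cols, dtype=object)
    for col in cols:
        sub = stratified if col == "total" else stratified[stratified["stratum"] == col]
        n = len(sub)
        table.loc["N", col] = n
        counts = sub["group"].value_counts()
        for g in BIRTH_GROUPS:
            c = int(counts.get(g, 0))
            table.loc[g, col] = _cell(c, n) if n else "- (-)"
    return table


def rate_by_stratum(
    stratified: pd.DataFrame,
    strat_field: str,
    *,
    group: str = "complete",
    bins: list[float] | None = None,
) -> pd.DataFrame:
    """Per-level rates of one linkage group (default complete) for all
    births and for liveborn singletons.

    *strat_field* is typically ``gestational_age_weeks`` or
    ``birthweight_g`` (supply *bins* to bin a continuous field). Levels
    with zero records are omitted with a logged note.
    """
    if strat_field not in stratified.columns:
        raise KeyError(f"unknown stratification field {strat_field!r}")
    df = stratified.copy()
    level = df[strat_field]
    if bins is not None:
        level = pd.cut(pd.to_numeric(level, errors="coerce"), bins=bins)
    df["_level"] = level

    rows = []
    for lev, sub in df.groupby("_level", observed=True, dropna=True):
        if len(sub) == 0:
            log.info("level %r has zero records; omitted", lev)
            continue
        live_single = sub[sub["stratum"] == "livebirth_singleton"]
        row = {
            "level": lev,
            "n_all": len(sub),
            "rate_all": pct(int((sub["group"] == group).sum()), len(sub)),
            "n_livesingleton": len(live_single),
            "rate_livesingleton": (
                pct(int((live_single["group"] == group).sum()), len(live_single))
                if len(live_single)
                else np.nan
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def identification_coverage(n_identified: int, n_reported: int) -> float:
    """Identified admissions as a one-decimal percentage of those reported
    in the birth records."""
    if n_reported == 0:
        raise ZeroDivisionError("zero reported denominator")
    return pct(n_identified, n_reported)


# variables whose value for the unlinked-hospital groups comes from the
# code-derived flags; None marks variables structurally unavailable there
_DEFAULT_VARIABLES: dict[str, dict[str, str | None]] = {
    "smoked": {"birth": "smoked", "hospital": None},
    "antenatal_care_ge15w": {"birth": "antenatal_care_ge15w", "hospital": None},
    "married": {"birth": "married", "hospital": None},
    "parity_0": {"birth": "parity_0", "hospital": None},
    "diabetes": {"birth": "diabetes", "hospital": "diabetes"},
    "hypertension": {"birth": "hypertension", "hospital": "hypertension"},
    "induction": {"birth": "induction", "hospital": "induction"},
    "caesarean": {"birth": "caesarean", "hospital": "caesarean"},
    "placenta_praevia": {"birth": "placenta_praevia", "hospital": "placenta_praevia"},
    "placental_abruption": {"birth": "placental_abruption", "hospital": "placental_abruption"},
    "duration_lt26w": {"birth": "duration_lt26w", "hospital": "duration_lt26w"},
    "private_hospital": {"birth": "private_hospital", "hospital": None},
    "preterm": {"birth": "preterm", "hospital": "preterm"},
    "apgar1_lt4": {"birth": "apgar1_lt4", "hospital": "apgar1_lt4"},
    "scn_nicu": {"birth": "scn_nicu", "hospital": None},
    "death_in_hospital": {"birth": "death_in_hospital", "hospital": None},
}


def _prepare_birth_vars(births: pd.DataFrame) -> pd.DataFrame:
    out = births.copy()
    if "parity" in out.columns:
        out["parity_0"] = (pd.to_numeric(out["parity"], errors="coerce") == 0).astype(int)
    if "gestational_age_weeks" in out.columns:
        ga = pd.to_numeric(out["gestational_age_weeks"], errors="coerce")
        out["duration_lt26w"] = (ga < 26).astype(int)
        if "preterm" not in out.columns:
            out["preterm"] = (ga < 37).astype(int)
    return out


def characteristics_table(
    stratified: pd.DataFrame,
    unlinked_maternal: pd.DataFrame | None = None,
    unlinked_infant: pd.DataFrame | None = None,
    variables: dict[str, dict[str, str | None]] | None = None,
    *,
    livesingleton_only: bool = True,
) -> pd.DataFrame:
    """Per-group counts and percentages of binary characteristics.

    Birth-record groups read the birth-record variables (the default
    precedence); the unlinked maternal/infant hospital groups read the
    code-derived flags, and cells for variables structurally unavailable in
    a hospital-only group are rendered ``- (-)``. By default restricted to
    liveborn singletons, the stratum characteristic comparisons are
    reported for.
    """
    variables = _DEFAULT_VARIABLES if variables is None else variables
    df = _prepare_birth_vars(stratified)
    if livesingleton_only:
        df = df[df["stratum"] == "livebirth_singleton"]

    groups: dict[str, tuple[pd.DataFrame, str]] = {
        g: (df[df["group"] == g], "birth") for g in BIRTH_GROUPS
    }
    if unlinked_maternal is not None:
        groups["unlinked_maternal_hospital"] = (unlinked_maternal, "hospital")
    if unlinked_infant is not None:
        groups["unlinked_infant_hospital"] = (unlinked_infant, "hospital")

    table = pd.DataFrame(index=list(variables), columns=list(groups), dtype=object)
    ns = {}
    for gname, (sub, source) in groups.items():
        ns[gname] = len(sub)
        for var, srcmap in variables.items():
            col = srcmap.get(source)
            if len(sub) == 0 or col is None or col not in sub.columns:
                table.loc[var, gname] = "- (-)"
                continue
            c = int(pd.to_numeric(sub[col], errors="coerce").fillna(0).astype(bool).sum())
            table.loc[var, gname] = _cell(c, len(sub))
    table.loc["N"] = [ns[g] for g in groups]
    return table


@dataclass(frozen=True)
class QualityReport:
    """Ground-truth linkage quality in per-1,000 units.

    ``missed_links_per_1000`` counts true record pairs absent from the
    declared link map, per 1,000 true pairs. ``false_positives_per_1000``
    counts declared links that are not true pairs, per 1,000 declared
    links.
    """

    missed_links_per_1000: float
    false_positives_per_1000: float
    n_true_pairs: int
    n_declared_links: int
    n_missed: int
    n_false: int


def evaluate_quality(
    declared: set[tuple[str, str]] | pd.DataFrame,
    truth: set[tuple[str, str]] | pd.DataFrame,
) -> QualityReport:
    """Compare a declared link map with ground-truth pairs.

    Both arguments are sets of ``(id_a, id_b)`` pairs or two-column frames
    (first two columns taken as the pair). Integer counts are formed first;
    rates are exact ratios scaled to per-1,000.
    """

    def to_set(obj) -> set[tuple[str, str]]:
        if isinstance(obj, pd.DataFrame):
            return set(zip(obj.iloc[:, 0].astype(str), obj.iloc[:, 1].astype(str)))
        return {(str(a), str(b)) for a, b in obj}

    d, t = to_set(declared), to_set(truth)
    n_missed = len(t - d)
    n_false = len(d - t)
    return QualityReport(
        missed_links_per_1000=1000.0 * n_missed / len(t) if t else 0.0,
        false_positives_per_1000=1000.0 * n_false / len(d) if d else 0.0,
        n_true_pairs=len(t),
        n_declared_links=len(d),
        n_missed=n_missed,
        n_false=n_false,
    )
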