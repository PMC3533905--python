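"""Synthetic mother-infant cohort generator with known ground truth.

Emulates the structure of a statutory birth-registration stream (one record
per infant, carrying both maternal and infant identifiers plus pregnancy
variables) and a hospital discharge stream (one delivery admission per
mother, one birth admission per live-born infant), as collected in an
Australian perinatal setting:

* private hospitals record names at their discretion, so hospital records
  from private hospitals have heavily missing name fields;
* stillbirths are recorded on the mother's admission and do not usually
  generate an infant admission (a small misclassification rate does, by
  default, produce an infant record for a stillbirth);
* multiple births share a delivery id, maternal identifiers, hospital and
  date of birth, differing in birth order and possibly sex.

Identifier fields on every emitted record are independently corrupted by a
configurable :class:`ErrorModel` (typos, name blanking, date-of-birth digit
swaps, alias substitution, address changes). Ground-truth entity ids and
true record pairs are returned alongside, never corrupted.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _wordlists as wl
from .identifier_prep import PersonIdentifiers

__all__ = [
    "CohortParams",
    "ErrorModel",
    "GroundTruth",
    "default_gestation_distribution",
    "generate_cohort",
    "corrupt_identifiers",
]


def default_gestation_distribution() -> dict[int, float]:
    """Distribution over completed weeks 20-42, peaked at 39-40 weeks.

    Roughly 5% of births fall below 37 weeks, matching a contemporary
    Australian preterm rate; the tail below 28 weeks is thin but nonzero
    so that gestation-stratified linkage reports are exercisable.
    """
    w = {
        20: 0.0004, 21: 0.0003, 22: 0.0003, 23: 0.0003, 24: 0.0004,
        25: 0.0004, 26: 0.0005, 27: 0.0006, 28: 0.0008, 29: 0.0010,
        30: 0.0014, 31: 0.0020, 32: 0.0030, 33: 0.0045, 34: 0.0075,
        35: 0.0120, 36: 0.0220, 37: 0.0520, 38: 0.1500, 39: 0.2600,
        40: 0.3000, 41: 0.1600, 42: 0.0206,
    }
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


# mean/SD birthweight (grams) by completed gestation week
_BW_TABLE: dict[int, tuple[float, float]] = {
    20: (350, 70), 21: (420, 80), 22: (500, 90), 23: (600, 100),
    24: (700, 110), 25: (800, 120), 26: (930, 130), 27: (1060, 140),
    28: (1200, 160), 29: (1350, 180), 30: (1500, 200), 31: (1700, 220),
    32: (1900, 240), 33: (2100, 260), 34: (2350, 280), 35: (2550, 300),
    36: (2750, 320), 37: (3000, 350), 38: (3200, 380), 39: (3350, 400),
    40: (3500, 420), 41: (3600, 430), 42: (3650, 450),
}


@dataclass(frozen=True)
class CohortParams:
    """Scale and outcome rates of the simulated delivery cohort."""

    n_deliveries: int = 1000
    multiple_pregnancy_rate: float = 0.016
    stillbirth_rate: float = 0.006
    private_hospital_rate: float = 0.25
    gestation_distribution: dict[int, float] = field(
        default_factory=default_gestation_distribution
    )
    seed: int = 0
    # deliveries with no maternal admission record (e.g. born before arrival
    # and never admitted); zero in the error-free oracle configuration
    maternal_nonadmission_rate: float = 0.002
    # stillbirths that nonetheless generate an infant admission record
    stillbirth_misclassification_rate: float = 0.015
    # admissions whose plurality/outcome diagnosis codes were not recorded
    code_missing_rate: float = 0.002
    start_date: str = "2001-01-01"
    period_days: int = 730

    def validate(self) -> None:
        if self.n_deliveries < 1:
            raise ValueError("n_deliveries must be >= 1")
        for name in (
            "multiple_pregnancy_rate", "stillbirth_rate", "private_hospital_rate",
            "maternal_nonadmission_rate", "stillbirth_misclassification_rate",
            "code_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        gd = self.gestation_distribution
        if not gd or any(not 20 <= k <= 42 for k in gd):
            raise ValueError("gestation_distribution keys must be weeks 20-42")
        if abs(sum(gd.values()) - 1.0) > 1e-6:
            raise ValueError("gestation_distribution must sum to 1")


@dataclass(frozen=True)
class ErrorModel:
    """Per-field identifier corruption rates.

    Name missingness is keyed to hospital type: private hospitals collect
    names at their discretion, so their records default to a much higher
    blanking rate than public hospitals.
    """

    typo_rate: float = 0.02
    name_missing_rate_public: float = 0.02
    name_missing_rate_private: float = 0.35
    dob_digit_swap_rate: float = 0.005
    alias_rate: float = 0.03
    address_change_rate: float = 0.05

    def validate(self) -> None:
        for name in (
            "typo_rate", "name_missing_rate_public", "name_missing_rate_private",
            "dob_digit_swap_rate", "alias_rate", "address_change_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def zero(cls) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroundTruth:
    """True entity ids and record pairs for a generated cohort.

    ``mother_pairs`` is keyed by delivery id because every birth record of a
    multiple delivery truly corresponds to the same maternal admission.
    """

    births: pd.DataFrame       # birth_record_id, delivery_id, mother/infant entity ids, flags
    mother_pairs: pd.DataFrame  # delivery_id, hosp_record_id
    infant_pairs: pd.DataFrame  # birth_record_id, hosp_record_id


# ---------------------------------------------------------------------------
# corruption primitives

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _typo(word: str, rng: np.random.Generator) -> str:
    """One character substitution or adjacent transposition."""
    if not word:
        return word
    chars = list(word)
    if len(chars) >= 2 and rng.random() < 0.5:
        i = int(rng.integers(0, len(chars) - 1))
        chars[i], chars[i + 1] = chars[i + 1], chars[i]
    else:
        i = int(rng.integers(0, len(chars)))
        chars[i] = _ALPHABET[int(rng.integers(0, 26))]
    return "".join(chars)


def _swap_dob_digits(dob: str, rng: np.random.Generator) -> str:
    """Transpose two adjacent digits of an ISO date (keyboard-style error)."""
    digits = [c for c in dob if c.isdigit()]
    if len(digits) != 8:
        return dob
    i = int(rng.integers(0, 7))
    digits[i], digits[i + 1] = digits[i + 1], digits[i]
    s = "".join(digits)
    return f"{s[:4]}-{s[4:6]}-{s[6:]}"


def corrupt_identifiers(
    ids: PersonIdentifiers,
    errors: ErrorModel,
    rng: np.random.Generator,
    *,
    private_hospital: bool = False,
) -> PersonIdentifiers:
    """Return a copy of *ids* with independent per-field perturbations.

    Applies, each with its own rate: character typos to name/address/MRN
    fields, blanking of both name fields (public or private rate according
    to *private_hospital*), an adjacent-digit transposition in the date of
    birth, substitution of the recorded surname by a known alias, and
    replacement of the address (a move between record collections). The
    entity identity is never altered; an all-zero model returns the input
    unchanged.
    """
    errors.validate()
    out = ids
    miss = (
        errors.name_missing_rate_private
        if private_hospital
        else errors.name_missing_rate_public
    )
    if miss and rng.random() < miss:
        out = replace(out, given_name="", surname="")
    else:
        if out.aliases and errors.alias_rate and rng.random() < errors.alias_rate:
            # record the other name as the alias of the one actually used
            out = replace(out, surname=out.aliases[0], aliases=(out.surname,))
        if errors.typo_rate:
            if out.given_name and rng.random() < errors.typo_rate:
                out = replace(out, given_name=_typo(out.given_name, rng))
            if out.surname and rng.random() < errors.typo_rate:
                out = replace(out, surname=_typo(out.surname, rng))
    if errors.typo_rate:
        if out.address and rng.random() < errors.typo_rate:
            out = replace(out, address=_typo(out.address, rng))
        if out.mrn and rng.random() < errors.typo_rate:
            out = replace(out, mrn=_typo(out.mrn, rng))
    if errors.dob_digit_swap_rate and out.dob and rng.random() < errors.dob_digit_swap_rate:
        out = replace(out, dob=_swap_dob_digits(out.dob, rng))
    if errors.address_change_rate and rng.random() < errors.address_change_rate:
        street = wl.sample_uniform(rng, wl.STREET_NAMES, 1)[0]
        suburb = wl.sample_uniform(rng, wl.SUBURBS, 1)[0]
        out = replace(out, address=f"{int(rng.integers(1, 400))} {street} {suburb}")
    return out


# ---------------------------------------------------------------------------
# cohort generation

_ID_COLS = [
    "given_name", "surname", "alias", "dob", "sex", "address",
    "country_of_birth", "mrn", "hospital_code",
]


def _sample_address(rng: np.random.Generator, n: int) -> np.ndarray:
    nums = rng.integers(1, 400, size=n)
    streets = wl.sample_uniform(rng, wl.STREET_NAMES, n)
    suburbs = wl.sample_uniform(rng, wl.SUBURBS, n)
    return np.array([f"{a} {b} {c}" for a, b, c in zip(nums, streets, suburbs)], dtype=object)


def _iso(dates: np.ndarray) -> np.ndarray:
    return np.array([d.isoformat() for d in dates], dtype=object)


def _corrupt_frame(
    df: pd.DataFrame,
    errors: ErrorModel,
    rng: np.random.Generator,
    private: np.ndarray,
    name_cols: tuple[str, str] = ("given_name", "surname"),
    alias_col: str | None = "alias",
    dob_cols: tuple[str, ...] = ("dob",),
) -> None:
    """In-place per-record corruption of an identifier frame."""
    n = len(df)
    given_c, sur_c = name_cols
    miss_rate = np.where(
        private, errors.name_missing_rate_private, errors.name_missing_rate_public
    )
    blank = rng.random(n) < miss_rate
    df.loc[blank, [given_c, sur_c]] = ""
    if alias_col is not None:
        use_alias = (~blank) & (df[alias_col].to_numpy() != "") & (
            rng.random(n) < errors.alias_rate
        )
        idx = np.flatnonzero(use_alias)
        if idx.size:
            sur = df[sur_c].to_numpy(copy=True)
            ali = df[alias_col].to_numpy(copy=True)
            sur[idx], ali[idx] = ali[idx], sur[idx].copy()
            df[sur_c] = sur
            df[alias_col] = ali
    for col in (given_c, sur_c, "address", "mrn"):
        hit = np.flatnonzero((rng.random(n) < errors.typo_rate) & (df[col].to_numpy() != ""))
        if hit.size:
            vals = df[col].to_numpy(copy=True)
            for i in hit:
                vals[i] = _typo(vals[i], rng)
            df[col] = vals
    for col in dob_cols:
        hit = np.flatnonzero(rng.random(n) < errors.dob_digit_swap_rate)
        if hit.size:
            vals = df[col].to_numpy(copy=True)
            for i in hit:
                vals[i] = _swap_dob_digits(vals[i], rng)
            df[col] = vals
    moved = np.flatnonzero(rng.random(n) < errors.address_change_rate)
    if moved.size:
        vals = df["address"].to_numpy(copy=True)
        vals[moved] = _sample_address(rng, moved.size)
        df["address"] = vals


def generate_cohort(
    params: CohortParams, errors: ErrorModel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate birth records, maternal and infant hospital records, and truth.

    Returns ``(births, maternal_hospital, infant_hospital, ground_truth)``.
    One birth record per infant born (multiples share a delivery id); one
    maternal admission per delivery bar the non-admission fraction; one
    infant admission per live birth plus misclassified stillbirths.
    """
    params.validate()
    errors = ErrorModel.zero() if errors is None else errors
    errors.validate()
    rng = np.random.default_rng(params.seed)
    nd = params.n_deliveries
    start = dt.date.fromisoformat(params.start_date)

    # --- delivery-level draws -------------------------------------------
    is_multiple = rng.random(nd) < params.multiple_pregnancy_rate
    n_babies = np.where(
        is_multiple, np.where(rng.random(nd) < 0.97, 2, 3), 1
    ).astype(int)
    private = rng.random(nd) < params.private_hospital_rate
    hospital = np.where(
        private,
        np.char.add("P", rng.integers(1, 26, nd).astype(str)),
        np.char.add("H", rng.integers(1, 61, nd).astype(str)),
    ).astype(object)

    birth_date = np.array(
        [start + dt.timedelta(days=int(d)) for d in rng.integers(0, params.period_days, nd)],
        dtype=object,
    )

    weeks = np.array(sorted(params.gestation_distribution), dtype=int)
    pw = np.array([params.gestation_distribution[w] for w in weeks])
    gest = rng.choice(weeks, size=nd, p=pw)

    # stillbirth risk falls steeply with gestation; the tilt scale is solved
    # so that the cohort-level expectation equals stillbirth_rate exactly
    rel = np.exp(-0.35 * (gest - 20.0))
    rel_w = np.exp(-0.35 * (weeks - 20.0))
    rate = params.stillbirth_rate
    if rate <= 0.0:
        p_still = np.zeros(nd)
    elif rate >= 1.0:
        p_still = np.ones(nd)
    else:
        lo, hi = 0.0, 1.0 / rel_w.min()
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if float((pw * np.minimum(1.0, mid * rel_w)).sum()) < rate:
                lo = mid
            else:
                hi = mid
        p_still = np.minimum(1.0, hi * rel)

    # mother identities
    m_entity = np.array([f"M{i:06d}" for i in range(nd)], dtype=object)
    m_given = wl.sample_weighted(rng, wl.GIVEN_NAMES_F, nd)
    m_surname = wl.sample_weighted(rng, wl.SURNAMES, nd)
    has_alias = rng.random(nd) < 0.30  # maiden/married name on file
    m_alias = np.where(has_alias, wl.sample_weighted(rng, wl.SURNAMES, nd), "")
    age_band = rng.choice(np.array([0, 1, 2]), size=nd, p=[0.185, 0.61, 0.205])
    age_years = np.select(
        [age_band == 0, age_band == 1, age_band == 2],
        [rng.integers(18, 26, nd), rng.integers(26, 35, nd), rng.integers(35, 44, nd)],
    )
    m_dob = np.array(
        [
            bd - dt.timedelta(days=int(a) * 365 + int(o))
            for bd, a, o in zip(birth_date, age_years, rng.integers(0, 365, nd))
        ],
        dtype=object,
    )
    m_address = _sample_address(rng, nd)
    m_country = wl.sample_weighted(rng, wl.COUNTRIES, nd)
    m_mrn = np.array([f"{v:07d}" for v in rng.integers(10**6, 10**7, nd)], dtype=object)

    # maternal characteristics (planted prevalences, drawn independently)
    parity = rng.choice(np.array([0, 1, 2, 3]), size=nd, p=[0.42, 0.335, 0.155, 0.09])
    smoked = rng.random(nd) < 0.145
    married = rng.random(nd) < 0.81
    antenatal_late = rng.random(nd) < 0.25
    diabetes = rng.random(nd) < 0.052
    hypertension = rng.random(nd) < 0.075
    caesarean = rng.random(nd) < 0.27
    induction = (~caesarean) & (rng.random(nd) < 0.33)
    praevia = rng.random(nd) < 0.005
    abruption = rng.random(nd) < 0.004
    seifa = rng.choice(np.array([1, 2, 3, 4, 5]), size=nd, p=[0.21, 0.19, 0.18, 0.18, 0.24])
    has_maternal_adm = rng.random(nd) >= params.maternal_nonadmission_rate

    adm_offset = rng.choice(np.array([0, 1, 2]), size=nd, p=[0.55, 0.35, 0.10])
    stay = rng.integers(1, 6, nd)
    m_admission = np.array(
        [bd - dt.timedelta(days=int(o)) for bd, o in zip(birth_date, adm_offset)],
        dtype=object,
    )
    m_separation = np.array(
        [bd + dt.timedelta(days=int(s)) for bd, s in zip(birth_date, stay)],
        dtype=object,
    )

    # --- infant-level expansion -----------------------------------------
    didx = np.repeat(np.arange(nd), n_babies)  # delivery index per birth record
    nb = didx.size
    order = np.concatenate([np.arange(1, k + 1) for k in n_babies])
    i_entity = np.array([f"I{i:06d}" for i in range(nb)], dtype=object)
    i_sex_m = rng.random(nb) < 0.515
    i_sex = np.where(i_sex_m, "M", "F").astype(object)
    i_given = np.empty(nb, dtype=object)
    i_given[i_sex_m] = wl.sample_weighted(rng, wl.GIVEN_NAMES_M, int(i_sex_m.sum()))
    i_given[~i_sex_m] = wl.sample_weighted(rng, wl.GIVEN_NAMES_F, int((~i_sex_m).sum()))
    i_mrn = np.array([f"{v:07d}" for v in rng.integers(10**6, 10**7, nb)], dtype=object)

    still = rng.random(nb) < p_still[didx]
    gest_b = gest[didx]
    bw_mean = np.array([_BW_TABLE[w][0] for w in gest_b])
    bw_sd = np.array([_BW_TABLE[w][1] for w in gest_b])
    mult_b = (n_babies[didx] > 1)
    bw = np.maximum(
        150, rng.normal(bw_mean * np.where(mult_b, 0.9, 1.0), bw_sd)
    ).round().astype(int)

    scn_nicu = (gest_b < 37) | (rng.random(nb) < 0.11)
    apgar_lt4 = (rng.random(nb) < 0.015) | (still & (rng.random(nb) < 0.5))
    death = (~still) & (gest_b < 28) & (rng.random(nb) < 0.25) | (
        (~still) & (rng.random(nb) < 0.002)
    )
    misclass = still & (rng.random(nb) < params.stillbirth_misclassification_rate)

    birth_record_id = np.array([f"B{i:06d}" for i in range(nb)], dtype=object)
    delivery_id = np.array([f"D{i:06d}" for i in range(nd)], dtype=object)[didx]

    births = pd.DataFrame(
        {
            "birth_record_id": birth_record_id,
            "delivery_id": delivery_id,
            "given_name": m_given[didx],
            "surname": m_surname[didx],
            "alias": m_alias[didx],
            "dob": _iso(m_dob[didx]),
            "sex": "F",
            "address": m_address[didx],
            "country_of_birth": m_country[didx],
            "mrn": m_mrn[didx],
            "hospital_code": hospital[didx],
            "private_hospital": private[didx].astype(int),
            "i_given_name": i_given,
            "i_surname": m_surname[didx],
            "i_dob": _iso(birth_date[didx]),
            "i_sex": i_sex,
            "i_mrn": i_mrn,
            "plurality": n_babies[didx],
            "birth_order": order,
            "gestational_age_weeks": gest_b,
            "birthweight_g": bw,
            "stillbirth": still.astype(int),
            "maternal_age": age_years[didx],
            "parity": parity[didx],
            "smoked": smoked[didx].astype(int),
            "married": married[didx].astype(int),
            "antenatal_care_ge15w": antenatal_late[didx].astype(int),
            "diabetes": diabetes[didx].astype(int),
            "hypertension": hypertension[didx].astype(int),
            "induction": induction[didx].astype(int),
            "caesarean": caesarean[didx].astype(int),
            "placenta_praevia": praevia[didx].astype(int),
            "placental_abruption": abruption[didx].astype(int),
            "seifa_quintile": seifa[didx],
            "scn_nicu": scn_nicu.astype(int),
            "apgar1_lt4": apgar_lt4.astype(int),
            "death_in_hospital": death.astype(int),
        }
    )

    # --- maternal hospital records --------------------------------------
    madm = np.flatnonzero(has_maternal_adm)
    nm = madm.size
    # delivery outcome per delivery for Z37 coding
    still_per_del = pd.Series(still).groupby(didx).sum().to_numpy()
    babies_per_del = n_babies

    def _z37(k: int, s: int) -> str:
        if k == 1:
            return "Z37.0" if s == 0 else "Z37.1"
        if k == 2:
            return {0: "Z37.2", 1: "Z37.3", 2: "Z37.4"}[min(s, 2)]
        return "Z37.5" if s == 0 else ("Z37.7" if s == k else "Z37.6")

    code_present = rng.random(nm) >= params.code_missing_rate
    diag_rows: list[str] = []
    proc_rows: list[str] = []
    for j, d in enumerate(madm):
        diags: list[str] = []
        procs: list[str] = []
        if code_present[j]:
            diags.append(_z37(int(babies_per_del[d]), int(still_per_del[d])))
            if babies_per_del[d] > 1:
                diags.append("O84")
            elif caesarean[d]:
                diags.append("O82")
            else:
                diags.append("O80")
        if caesarean[d]:
            procs.append("16520")
        elif induction[d]:
            procs.append("90465")
        else:
            procs.append("90467")
        if gest[d] < 37:
            diags.append("O60.1")
        if gest[d] < 26:
            diags.append("O90.1")
        if diabetes[d]:
            diags.append("O24.4")
        if hypertension[d]:
            diags.append("O13")
        if praevia[d]:
            diags.append("O44.1")
        if abruption[d]:
            diags.append("O45.9")
        diag_rows.append(" ".join(diags))
        proc_rows.append(" ".join(procs))

    maternal = pd.DataFrame(
        {
            "hosp_record_id": [f"MH{i:06d}" for i in range(nm)],
            "given_name": m_given[madm],
            "surname": m_surname[madm],
            "alias": m_alias[madm],
            "dob": _iso(m_dob[madm]),
            "sex": "F",
            "address": m_address[madm],
            "country_of_birth": m_country[madm],
            "mrn": m_mrn[madm],
            "hospital_code": hospital[madm],
            "admission_date": _iso(m_admission[madm]),
            "separation_date": _iso(m_separation[madm]),
            "age_years": age_years[madm],
            "age_days": np.nan,
            "birthweight_g": np.nan,
            "source_of_referral": "",
            "admission_order": 2,  # not the person's first-ever admission
            "plurality": babies_per_del[madm],
            "birth_order": 0,
            "diagnosis_codes": diag_rows,
            "procedure_codes": proc_rows,
        }
    )

    # --- infant hospital records ----------------------------------------
    gets_adm = (~still) | misclass
    iadm = np.flatnonzero(gets_adm)
    ni = iadm.size
    adm_lag = rng.choice(np.array([0, 1]), size=ni, p=[0.9, 0.1])
    i_admission = np.array(
        [birth_date[didx[i]] + dt.timedelta(days=int(l)) for i, l in zip(iadm, adm_lag)],
        dtype=object,
    )
    i_stay = rng.integers(1, 8, ni)
    i_separation = np.array(
        [a + dt.timedelta(days=int(s)) for a, s in zip(i_admission, i_stay)],
        dtype=object,
    )
    born_before_arrival = rng.random(ni) < 0.01
    icode_present = rng.random(ni) >= params.code_missing_rate

    def _z38(k: int, bba: bool) -> str:
        if k == 1:
            return "Z38.1" if bba else "Z38.0"
        if k == 2:
            return "Z38.4" if bba else "Z38.3"
        return "Z38.7" if bba else "Z38.6"

    idiag_rows: list[str] = []
    for j, i in enumerate(iadm):
        diags = []
        if icode_present[j]:
            diags.append(_z38(int(n_babies[didx[i]]), bool(born_before_arrival[j])))
        if gest_b[i] < 28:
            diags.append("P07.2")
        elif gest_b[i] < 37:
            diags.append("P07.3")
        if apgar_lt4[i]:
            diags.append("P20.1")
        idiag_rows.append(" ".join(diags))

    infant = pd.DataFrame(
        {
            "hosp_record_id": [f"IH{i:06d}" for i in range(ni)],
            "given_name": i_given[iadm],
            "surname": m_surname[didx[iadm]],
            "alias": "",
            "dob": _iso(birth_date[didx[iadm]]),
            "sex": i_sex[iadm],
            "address": m_address[didx[iadm]],
            "country_of_birth": "AUSTRALIA",
            "mrn": i_mrn[iadm],
            "hospital_code": hospital[didx[iadm]],
            "admission_date": _iso(i_admission),
            "separation_date": _iso(i_separation),
            "age_years": 0,
            "age_days": adm_lag,
            "birthweight_g": bw[iadm].astype(float),
            "source_of_referral": np.where(
                born_before_arrival, "other", "born in hospital"
            ),
            "admission_order": 1,
            "plurality": n_babies[didx[iadm]],
            "birth_order": order[iadm],
            "diagnosis_codes": idiag_rows,
            "procedure_codes": "",
        }
    )
    # a small fraction of records lack a recorded birthweight
    bw_missing = rng.random(ni) < 0.01
    infant.loc[bw_missing, "birthweight_g"] = np.nan

    # --- corruption ------------------------------------------------------
    _corrupt_frame(births, errors, rng, private[didx])
    # infant identifiers on the birth record: typos/DOB swaps only (the
    # registration always carries the infant's particulars)
    for col in ("i_given_name", "i_surname", "i_mrn"):
        hit = np.flatnonzero((rng.random(nb) < errors.typo_rate) & (births[col].to_numpy() != ""))
        if hit.size:
            vals = births[col].to_numpy(copy=True)
            for i in hit:
                vals[i] = _typo(vals[i], rng)
            births[col] = vals
    hit = np.flatnonzero(rng.random(nb) < errors.dob_digit_swap_rate)
    if hit.size:
        vals = births["i_dob"].to_numpy(copy=True)
        for i in hit:
            vals[i] = _swap_dob_digits(vals[i], rng)
        births["i_dob"] = vals

    _corrupt_frame(maternal, errors, rng, private[madm])
    _corrupt_frame(infant, errors, rng, private[didx[iadm]], alias_col=None)

    truth = GroundTruth(
        births=pd.DataFrame(
            {
                "birth_record_id": birth_record_id,
                "delivery_id": delivery_id,
                "mother_entity_id": m_entity[didx],
                "infant_entity_id": i_entity,
                "stillbirth": still.astype(int),
                "misclassified_stillbirth": misclass.astype(int),
            }
        ),
        mother_pairs=pd.DataFrame(
            {
                "delivery_id": np.array([f"D{i:06d}" for i in madm], dtype=object),
                "hosp_record_id": maternal["hosp_record_id"].to_numpy(),
            }
        ),
        infant_pairs=pd.DataFrame(
            {
                "birth_record_id": birth_record_id[iadm],
                "hosp_record_id": infant["hosp_record_id"].to_numpy(),
            }
        ),
    )
    return births, maternal, infant, truth
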