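"""Assignment of birth and hospital records to the six linkage groups.

Each birth record falls into exactly one of four mutually exclusive groups
according to which of its two hospital links exist: ``complete`` (both the
mother's delivery admission and the infant's birth admission linked),
``mothers_only``, ``infants_only``, or ``unlinked_birth``. Identified birth
admissions that linked to no birth record form the remaining two groups,
``unlinked_maternal_hospital`` and ``unlinked_infant_hospital``. Group
assignment is per birth record (per infant), so one multiple delivery can
contribute records to different groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["BIRTH_GROUPS", "assign_groups", "stratify"]

BIRTH_GROUPS = ("complete", "mothers_only", "infants_only", "unlinked_birth")


def assign_groups(
    births: pd.DataFrame,
    mother_links: pd.DataFrame,
    infant_links: pd.DataFrame,
    maternal_admissions: pd.DataFrame | None = None,
    infant_admissions: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Combine the two link maps into a linkage-group table.

    ``mother_links`` maps ``delivery_id`` to a maternal hospital record id
    (one maternal admission serves every birth record of its delivery);
    ``infant_links`` maps ``birth_record_id`` to an infant hospital record
    id. The optional admission frames (records already identified as birth
    admissions) supply the two unlinked-hospital groups.

    Returns ``{"births": table, "unlinked_maternal": ids, "unlinked_infant": ids}``
    where the birth table adds ``group``, ``mother_hosp_id``, ``infant_hosp_id``.
    """
    for links, key in ((mother_links, "delivery_id"), (infant_links, "birth_record_id")):
        if len(links):
            unknown = ~links[key].isin(births[key])
            if unknown.any():
                raise KeyError(
                    f"link map references unknown {key}: {links.loc[unknown, key].iloc[0]!r}"
                )

    out = births.copy()
    m = mother_links.rename(columns={"record_id_b": "mother_hosp_id"})
    i = infant_links.rename(columns={"record_id_b": "infant_hosp_id"})
    out = out.merge(m[["delivery_id", "mother_hosp_id"]], on="delivery_id", how="left")
    out = out.merge(
        i[["birth_record_id", "infant_hosp_id"]], on="birth_record_id", how="left"
    )
    has_m = out["mother_hosp_id"].notna()
    has_i = out["infant_hosp_id"].notna()
    out["group"] = np.select(
        [has_m & has_i, has_m, has_i],
        ["complete", "mothers_only", "infants_only"],
        "unlinked_birth",
    )

    def unlinked(adms: pd.DataFrame | None, linked_ids: pd.Series) -> pd.DataFrame:
        if adms is None:
            return pd.DataFrame(columns=["hosp_record_id"])
        keep = ~adms["hosp_record_id"].isin(set(linked_ids.dropna()))
        return adms.loc[keep].reset_index(drop=True)

    return {
        "births": out,
        "unlinked_maternal": unlinked(maternal_admissions, out["mother_hosp_id"]),
        "unlinked_infant": unlinked(infant_admissions, out["infant_hosp_id"]),
    }


def stratify(group_table: pd.DataFrame) -> pd.DataFrame:
    """Attach the plurality x live/stillbirth stratum to each birth record.

    Strata are ``livebirth_singleton``, ``livebirth_multiple``,
    ``stillbirth_singleton``, ``stillbirth_multiple``; records whose
    plurality or outcome cannot be determined fall in an explicit
    ``unknown`` stratum rather than being dropped.
    """
    out = group_table.copy()
    plur = pd.to_numeric(out.get("plurality"), errors="coerce")
    still = pd.to_numeric(out.get("stillbirth"), errors="coerce")
    known = plur.notna() & still.notna()
    status = np.where(still == 1, "stillbirth", "livebirth")
    kind = np.where(plur > 1, "multiple", "singleton")
    out["stratum"] = np.where(known, np.char.add(np.char.add(status, "_"), kind), "unknown")
    return out
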