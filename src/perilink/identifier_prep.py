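"""Standardization, parsing and phonetic encoding of personal identifiers.

Record pairs are compared on normalized fields; phonetic codes (American
Soundex and NYSIIS) let name clues tolerate spelling variation, so that
e.g. ``Robert`` and ``Rupert`` receive the same Soundex code. Empty or
non-alphabetic input encodes to :data:`EMPTY_CODE`, a sentinel that clue
comparators treat as missing rather than as a matchable value.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

__all__ = [
    "EMPTY_CODE",
    "PersonIdentifiers",
    "StandardizedIdentifiers",
    "normalize_name",
    "normalize_address",
    "normalize_identifiers",
    "soundex",
    "nysiis",
]

#: Sentinel phonetic code for empty/non-alphabetic input. Distinct from any
#: real code (real codes start with a letter) and treated as missing by clues.
EMPTY_CODE = ""

_VOWELS = frozenset("AEIOU")

_SOUNDEX_MAP = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}

_PUNCT_RE = re.compile(r"[^A-Z0-9 ]+")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class PersonIdentifiers:
    """Raw matching fields of one record, as collected."""

    given_name: str = ""
    surname: str = ""
    dob: str = ""  # ISO-8601 calendar date or empty
    sex: str = ""
    address: str = ""
    country_of_birth: str = ""
    hospital_code: str = ""
    mrn: str = ""
    aliases: tuple[str, ...] = ()


@dataclass(frozen=True)
class StandardizedIdentifiers:
    """Identifier fields after normalization, plus phonetic codes."""

    given_name_norm: str = ""
    surname_norm: str = ""
    given_name_soundex: str = EMPTY_CODE
    surname_soundex: str = EMPTY_CODE
    given_name_nysiis: str = EMPTY_CODE
    surname_nysiis: str = EMPTY_CODE
    dob: str = ""
    sex: str = "unknown"
    address_norm: str = ""
    country_of_birth: str = ""
    hospital_code: str = ""
    mrn: str = ""
    aliases: tuple[str, ...] = field(default_factory=tuple)


def _strip_accents(text: str) -> str:
    # Transliterate diacritics to their ASCII base letter before encoding.
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def normalize_name(name: str) -> str:
    """Uppercase, transliterate, strip punctuation, collapse whitespace.

    Idempotent: ``normalize_name(normalize_name(x)) == normalize_name(x)``.
    ``" O'Brien "`` becomes ``"OBRIEN"``.
    """
    up = _strip_accents(str(name)).upper()
    up = _PUNCT_RE.sub("", up)
    return _WS_RE.sub(" ", up).strip()


def normalize_address(address: str) -> str:
    """Tokenized address: punctuation becomes a separator, then collapse."""
    up = _strip_accents(str(address)).upper()
    up = re.sub(r"[^A-Z0-9]+", " ", up)
    return _WS_RE.sub(" ", up).strip()


def _alpha_only(word: str) -> str:
    return re.sub(r"[^A-Z]", "", _strip_accents(str(word)).upper())


def soundex(word: str) -> str:
    """American Soundex code (letter + 3 digits) of *word*.

    Vowels (and Y) separate repeated consonant codes; H and W are
    transparent, so consonants with the same code separated only by H/W
    are coded once ("Ashcraft" -> "A261"). Empty or non-alphabetic input
    returns :data:`EMPTY_CODE`.
    """
    letters = _alpha_only(word)
    if not letters:
        return EMPTY_CODE
    first = letters[0]
    code = first
    last_digit = _SOUNDEX_MAP.get(first, "")
    for ch in letters[1:]:
        if ch in "HW":
            continue  # transparent: does not reset the previous code
        digit = _SOUNDEX_MAP.get(ch, "")
        if digit == "":
            last_digit = ""  # vowel resets
            continue
        if digit != last_digit:
            code += digit
            if len(code) == 4:
                break
        last_digit = digit
    return (code + "000")[:4]


def nysiis(word: str) -> str:
    """NYSIIS phonetic code of *word* (untruncated variant).

    Follows the published New York State Identification and Intelligence
    System rules: leading MAC->MCC, KN->NN, K->C, PH/PF->FF, SCH->SSS;
    trailing EE/IE->Y and DT/RT/RD/NT/ND->D; then a left-to-right scan
    mapping vowels to A (EV->AF), Q->G, Z->S, M->N, KN->N, K->C,
    SCH->SSS, PH->FF, and context rules for H and W, dropping adjacent
    duplicates; finally trailing S is dropped, AY->Y, trailing A dropped.
    """
    letters = _alpha_only(word)
    if not letters:
        return EMPTY_CODE
    w = letters
    # leading transforms
    if w.startswith("MAC"):
        w = "MCC" + w[3:]
    elif w.startswith("KN"):
        w = "NN" + w[2:]
    elif w.startswith("K"):
        w = "C" + w[1:]
    elif w.startswith(("PH", "PF")):
        w = "FF" + w[2:]
    elif w.startswith("SCH"):
        w = "SSS" + w[3:]
    # trailing transforms
    if w.endswith(("EE", "IE")):
        w = w[:-2] + "Y"
    elif w.endswith(("DT", "RT", "RD", "NT", "ND")):
        w = w[:-2] + "D"

    key = w[0]
    chars = list(w)
    i = 1
    n = len(chars)
    while i < n:
        ch = chars[i]
        if ch in _VOWELS:
            if ch == "E" and i + 1 < n and chars[i + 1] == "V":
                chars[i], chars[i + 1] = "A", "F"
            else:
                chars[i] = "A"
        elif ch == "Q":
            chars[i] = "G"
        elif ch == "Z":
            chars[i] = "S"
        elif ch == "M":
            chars[i] = "N"
        elif ch == "K":
            if i + 1 < n and chars[i + 1] == "N":
                chars[i] = "N"
            else:
                chars[i] = "C"
        elif ch == "S" and chars[i : i + 3] == ["S", "C", "H"]:
            chars[i : i + 3] = ["S", "S", "S"]
        elif ch == "P" and i + 1 < n and chars[i + 1] == "H":
            chars[i : i + 2] = ["F", "F"]
        elif ch == "H":
            prev = chars[i - 1]
            nxt = chars[i + 1] if i + 1 < n else ""
            if prev not in _VOWELS or (nxt and nxt not in _VOWELS):
                chars[i] = prev
        elif ch == "W":
            if chars[i - 1] in _VOWELS:
                chars[i] = chars[i - 1]
        if chars[i] != key[-1]:
            key += chars[i]
        i += 1

    if len(key) > 1 and key.endswith("S"):
        key = key[:-1]
    if key.endswith("AY"):
        key = key[:-2] + "Y"
    if len(key) > 1 and key.endswith("A"):
        key = key[:-1]
    return key


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().upper()
    if s in {"M", "MALE", "1"}:
        return "M"
    if s in {"F", "FEMALE", "2"}:
        return "F"
    return "unknown"


def normalize_identifiers(ids: PersonIdentifiers) -> StandardizedIdentifiers:
    """Standardize all matching fields of one record and attach phonetic codes.

    Deterministic and idempotent; aliases are carried as a normalized tuple.
    """
    given = normalize_name(ids.given_name)
    surname = normalize_name(ids.surname)
    return StandardizedIdentifiers(
        given_name_norm=given,
        surname_norm=surname,
        given_name_soundex=soundex(given),
        surname_soundex=soundex(surname),
        given_name_nysiis=nysiis(given),
        surname_nysiis=nysiis(surname),
        dob=str(ids.dob).strip(),
        sex=_norm_sex(ids.sex),
        address_norm=normalize_address(ids.address),
        country_of_birth=normalize_name(ids.country_of_birth),
        hospital_code=str(ids.hospital_code).strip().upper(),
        mrn=str(ids.mrn).strip().upper(),
        aliases=tuple(normalize_name(a) for a in ids.aliases if normalize_name(a)),
    )
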