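"""Bundled name/address frequency lists for the synthetic cohort generator.

Frequencies are rough Anglo-Australian rank weights (Zipf-like), chosen so
that common surnames collide on phonetic codes at realistic rates (several
SMITH/SMYTH, CLARK/CLARKE, etc. per few thousand records). They are not a
census product; only the shape matters for exercising the linkage.
"""

from __future__ import annotations

import numpy as np

# (name, relative weight); weights need not sum to 1.
SURNAMES: list[tuple[str, float]] = [
    ("SMITH", 100), ("JONES", 80), ("WILLIAMS", 75), ("BROWN", 70),
    ("WILSON", 65), ("TAYLOR", 62), ("JOHNSON", 55), ("WHITE", 50),
    ("MARTIN", 48), ("ANDERSON", 46), ("THOMPSON", 44), ("NGUYEN", 43),
    ("THOMAS", 40), ("WALKER", 38), ("HARRIS", 36), ("LEE", 35),
    ("RYAN", 33), ("ROBINSON", 32), ("KELLY", 31), ("KING", 30),
    ("DAVIS", 29), ("WRIGHT", 28), ("EVANS", 27), ("ROBERTS", 26),
    ("GREEN", 25), ("HALL", 24), ("WOOD", 23), ("JACKSON", 22),
    ("CLARKE", 21), ("CLARK", 20), ("PATEL", 20), ("KHAN", 19),
    ("LEWIS", 18), ("JAMES", 17), ("PHILLIPS", 16), ("MASON", 15),
    ("MITCHELL", 15), ("YOUNG", 14), ("ALLEN", 13), ("BELL", 13),
    ("COOPER", 12), ("MURPHY", 12), ("BAILEY", 11), ("COLLINS", 11),
    ("MORRIS", 10), ("CAMPBELL", 10), ("SCOTT", 10), ("TURNER", 10),
    ("HILL", 9), ("WARD", 9), ("WATSON", 9), ("MORGAN", 9),
    ("SMYTH", 8), ("MACDONALD", 8), ("MCDONALD", 8), ("STEWART", 8),
    ("GRAY", 7), ("GREY", 7), ("SINGH", 7), ("CHEN", 7),
    ("WANG", 6), ("LIU", 6), ("TRAN", 6), ("PHAM", 6),
    ("OBRIEN", 6), ("O'BRIEN", 5), ("BYRNE", 5), ("WALSH", 5),
    ("DOYLE", 5), ("REID", 5), ("READ", 4), ("REED", 4),
    ("HUGHES", 4), ("EDWARDS", 4), ("HARRISON", 4), ("GIBSON", 4),
    ("MILLS", 4), ("FOSTER", 4), ("BUTLER", 4), ("BARNES", 4),
    ("FISHER", 3), ("HENDERSON", 3), ("COLE", 3), ("PEARCE", 3),
    ("PIERCE", 3), ("GRANT", 3), ("MARSHALL", 3), ("SIMPSON", 3),
    ("ELLIS", 3), ("PALMER", 3), ("STEVENS", 3), ("STEPHENS", 3),
    ("KAUR", 3), ("ALI", 3), ("HUSSAIN", 3), ("KIM", 3),
    ("PARK", 2), ("ZHANG", 2), ("LI", 2), ("COSTA", 2),
    ("ROSSI", 2), ("RUSSO", 2), ("PAPADOPOULOS", 2), ("KATSAROS", 2),
    ("SCHMIDT", 2), ("MULLER", 2), ("JENSEN", 2), ("HANSEN", 2),
    ("VAN DER BERG", 2), ("DE SILVA", 2), ("FERNANDO", 2), ("PERERA", 2),
]

GIVEN_NAMES_F: list[tuple[str, float]] = [
    ("SARAH", 60), ("EMMA", 58), ("JESSICA", 55), ("OLIVIA", 52),
    ("CHLOE", 48), ("SOPHIE", 46), ("EMILY", 45), ("HANNAH", 42),
    ("GRACE", 40), ("LUCY", 38), ("KATE", 36), ("KATHERINE", 34),
    ("CATHERINE", 32), ("KATHRYN", 12), ("REBECCA", 30), ("LAUREN", 29),
    ("MICHELLE", 28), ("LISA", 27), ("KAREN", 26), ("SUSAN", 25),
    ("JENNIFER", 24), ("AMANDA", 23), ("MELISSA", 22), ("NICOLE", 21),
    ("RACHEL", 20), ("RACHAEL", 8), ("SAMANTHA", 19), ("NATALIE", 18),
    ("CLAIRE", 17), ("CLARE", 7), ("ANNA", 16), ("ANNE", 15),
    ("ANN", 6), ("MARIA", 14), ("MARY", 13), ("MARIE", 12),
    ("ELIZABETH", 12), ("VICTORIA", 11), ("ALICE", 10), ("AMY", 10),
    ("JULIA", 9), ("JULIE", 9), ("HELEN", 9), ("LEAH", 8),
    ("GEORGIA", 8), ("ZOE", 8), ("HOLLY", 7), ("ABBEY", 5),
    ("ABBIE", 4), ("ABBY", 4), ("MIA", 7), ("ISABELLA", 7),
    ("ISABEL", 5), ("ISOBEL", 3), ("CHARLOTTE", 7), ("RUBY", 6),
    ("ELLA", 6), ("AVA", 6), ("SIENNA", 5), ("MATILDA", 5),
    ("PRIYA", 4), ("ANITA", 4), ("MEI", 3), ("LING", 3),
    ("FATIMA", 3), ("AISHA", 3), ("YASMIN", 3), ("JASMINE", 4),
    ("KIM", 3), ("LAN", 2), ("HUONG", 2), ("THI", 2),
    ("ELENI", 2), ("SOFIA", 3), ("SOPHIA", 4), ("INGRID", 2),
]

GIVEN_NAMES_M: list[tuple[str, float]] = [
    ("JACK", 60), ("WILLIAM", 58), ("JAMES", 56), ("JOSHUA", 52),
    ("LACHLAN", 50), ("THOMAS", 48), ("ETHAN", 44), ("DANIEL", 42),
    ("SAMUEL", 40), ("RYAN", 38), ("BENJAMIN", 36), ("MICHAEL", 35),
    ("MATTHEW", 34), ("LUKE", 32), ("ALEXANDER", 30), ("HARRISON", 28),
    ("OLIVER", 27), ("NOAH", 26), ("DYLAN", 25), ("JAKE", 24),
    ("LIAM", 23), ("NICHOLAS", 22), ("NICOLAS", 6), ("HENRY", 21),
    ("CHARLES", 20), ("GEORGE", 19), ("EDWARD", 18), ("PATRICK", 17),
    ("CONNOR", 16), ("CONOR", 5), ("SEAN", 15), ("SHAUN", 6),
    ("SHANE", 8), ("AIDAN", 12), ("AIDEN", 7), ("CALLUM", 11),
    ("ROBERT", 11), ("RUPERT", 2), ("RICHARD", 10), ("STEPHEN", 10),
    ("STEVEN", 9), ("PHILIP", 8), ("PHILLIP", 6), ("ANDREW", 12),
    ("ANTHONY", 11), ("MARK", 10), ("MARC", 3), ("PAUL", 9),
    ("PETER", 9), ("DAVID", 12), ("JOHN", 12), ("JON", 3),
    ("JONATHAN", 8), ("CHRISTOPHER", 10), ("KRISTOPHER", 2), ("SIMON", 7),
    ("TIMOTHY", 7), ("ADAM", 7), ("NATHAN", 7), ("JACOB", 8),
    ("ISAAC", 6), ("MOHAMMED", 5), ("MUHAMMAD", 4), ("MOHAMMAD", 3),
    ("OMAR", 3), ("ALI", 3), ("WEI", 3), ("JIN", 2),
    ("MINH", 2), ("QUAN", 2), ("DIMITRI", 2), ("STEFAN", 2),
    ("MARCO", 2), ("ANTONIO", 2), ("CARLOS", 2), ("RAJ", 3),
]

STREET_NAMES: list[str] = [
    "HIGH ST", "CHURCH ST", "STATION ST", "GEORGE ST", "KING ST",
    "QUEEN ST", "VICTORIA RD", "ALBERT ST", "ELIZABETH ST", "MAIN RD",
    "PARK AVE", "BEACH RD", "RAILWAY PDE", "SHORT ST", "WILLIAM ST",
    "MARKET ST", "BRIDGE RD", "RIVER RD", "FOREST WAY", "HILL ST",
    "CHAPEL ST", "MILL RD", "SCHOOL LANE", "GARDEN GROVE", "ORCHARD RD",
    "WATTLE CRES", "BANKSIA AVE", "ACACIA DR", "EUCALYPT CT", "GUM TREE RD",
    "JACARANDA PL", "BOTANY RD", "PACIFIC HWY", "PRINCES HWY", "HUME HWY",
    "OXFORD ST", "CROWN ST", "PITT ST", "MACQUARIE ST", "COWPER ST",
]

SUBURBS: list[str] = [
    "NEWTOWN", "PARRAMATTA", "BLACKTOWN", "LIVERPOOL", "PENRITH",
    "HORNSBY", "CHATSWOOD", "BONDI", "RANDWICK", "MARRICKVILLE",
    "BANKSTOWN", "FAIRFIELD", "CAMPBELLTOWN", "GOSFORD", "WOLLONGONG",
    "NEWCASTLE", "MAITLAND", "DUBBO", "ORANGE", "BATHURST",
    "WAGGA WAGGA", "ALBURY", "TAMWORTH", "ARMIDALE", "LISMORE",
    "COFFS HARBOUR", "PORT MACQUARIE", "TAREE", "NOWRA", "GOULBURN",
]

# country of birth with relative weights; roughly 71-72% Australia-born.
COUNTRIES: list[tuple[str, float]] = [
    ("AUSTRALIA", 715), ("ENGLAND", 40), ("NEW ZEALAND", 35), ("CHINA", 30),
    ("INDIA", 28), ("VIETNAM", 25), ("PHILIPPINES", 20), ("LEBANON", 18),
    ("ITALY", 12), ("GREECE", 10), ("SOUTH AFRICA", 10), ("KOREA", 9),
    ("FIJI", 8), ("IRAQ", 7), ("GERMANY", 6), ("IRELAND", 6),
    ("SRI LANKA", 6), ("INDONESIA", 5), ("MALAYSIA", 5), ("OTHER", 5),
]


def _weights(pairs: list[tuple[str, float]]) -> tuple[np.ndarray, np.ndarray]:
    names = np.array([p[0] for p in pairs], dtype=object)
    w = np.array([p[1] for p in pairs], dtype=float)
    return names, w / w.sum()


def sample_weighted(rng: np.random.Generator, pairs: list[tuple[str, float]], size: int) -> np.ndarray:
    names, p = _weights(pairs)
    return rng.choice(names, size=size, p=p)


def sample_uniform(rng: np.random.Generator, items: list[str], size: int) -> np.ndarray:
    return rng.choice(np.array(items, dtype=object), size=size)
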