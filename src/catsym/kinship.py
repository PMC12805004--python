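"""Kin types as feature bundles and category-size extraction from
term-extension tables.

Kin-type codes follow the compact genealogical grammar common in kinship
typology: an optional lowercase speaker-sex prefix (``m``/``f``), an
optional relative-age marker (``e`` elder / ``y`` younger), then an
uppercase chain of relatives read left to right — ``F`` father, ``M``
mother, ``B`` brother, ``Z`` sister, ``S`` son, ``D`` daughter, ``G``
sibling of unspecified sex.  So ``meB`` is a male speaker's elder brother,
``MZ`` is mother's sister, ``fZD`` is a female speaker's sister's
daughter.  Unknown codes are rejected loudly.

The size of a language's category system for a kinship subdomain is the
number of *distinct term extensions* over that subdomain's kin-type
inventory: every term that can refer to at least one inventory type is
kept, its extension is restricted to the inventory, and terms with
identical restricted extensions count as a single category (synonyms and
orthographic variants collapse; overlapping categories are permitted and
each distinct extension counts once).

The sibling inventory is fixed: the 12 speaker-sex × relative-age ×
referent-sex specific types (meB, meZ, myB, myZ, mB, mZ and the female-
speaker analogues).  The underspecified covers mG and fG are deliberately
excluded, since each subdomain inventory should contain only proper
subsets of itself as candidate extensions.  Inventories for the other five
subdomains are editable package defaults reconstructed from standard core
kin-type lists; see docs/methods.md.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "KinType",
    "TermExtension",
    "EmptySubdomainError",
    "parse_kin_code",
    "subdomain_kin_types",
    "extract_category_system",
    "read_kin_table",
    "sibling_feature_bijection",
    "SIBLING_CODES",
    "DEFAULT_INVENTORIES",
    "SUBDOMAINS",
]

_CODE_RE = re.compile(r"^([mf])?([ey])?([FMBZSDG]+)$")

_REFERENT_SEX = {
    "F": "male", "M": "female", "B": "male", "Z": "female",
    "S": "male", "D": "female", "G": "unspecified",
}
_GENERATION = {"F": 1, "M": 1, "B": 0, "Z": 0, "G": 0, "S": -1, "D": -1}
_SPEAKER = {"m": "male", "f": "female", None: "unspecified"}
_AGE = {"e": "elder", "y": "younger", None: "unspecified"}


class EmptySubdomainError(ValueError):
    """A language's term table has no term covering the subdomain."""


@dataclass(frozen=True)
class KinType:
    """A genealogical kin type decomposed into its distinguishing features."""

    code: str
    speaker_sex: str
    referent_sex: str
    relative_age: str
    generation: int
    connecting_relative_sex: str

    def __str__(self) -> str:
        return self.code


def parse_kin_code(code: str) -> KinType:
    """Parse a kin-type code into its feature bundle.

    Raises ``ValueError`` for anything outside the grammar — silent
    acceptance of a typo would silently corrupt category counts.
    """
    m = _CODE_RE.match(code)
    if not m:
        raise ValueError(f"unknown kin-type code {code!r}")
    speaker, age, chain = m.groups()
    generation = sum(_GENERATION[c] for c in chain)
    referent_sex = _REFERENT_SEX[chain[-1]]
    if len(chain) >= 2 and chain[0] in ("F", "M"):
        connecting = "paternal" if chain[0] == "F" else "maternal"
    else:
        connecting = "unspecified"
    return KinType(
        code=code,
        speaker_sex=_SPEAKER[speaker],
        referent_sex=referent_sex,
        relative_age=_AGE[age],
        generation=generation,
        connecting_relative_sex=connecting,
    )


#: The fixed 12-type sibling inventory: speaker sex crossed with referent
#: sex, at three age specifications (elder, younger, unspecified).  The
#: sex-underspecified covers mG and fG are deliberately excluded.
SIBLING_CODES = (
    "mB", "mZ", "meB", "meZ", "myB", "myZ",
    "fB", "fZ", "feB", "feZ", "fyB", "fyZ",
)

# Default inventories for the remaining five subdomains.  These are
# reconstructions from standard core kin-type lists (paternal/maternal and
# speaker-sex distinctions where the literature records them as contrastive)
# and are shipped as editable defaults rather than fixed definitions.
DEFAULT_INVENTORIES: dict[str, tuple[str, ...]] = {
    "siblings": SIBLING_CODES,
    "parents_siblings": ("FB", "FZ", "MB", "MZ"),
    "grandparents": ("FF", "FM", "MF", "MM"),
    "grandchildren": ("SS", "SD", "DS", "DD"),
    "nieces_nephews": (
        "mBS", "mBD", "mZS", "mZD", "fBS", "fBD", "fZS", "fZD",
    ),
    "cousins": ("FBS", "FBD", "FZS", "FZD", "MBS", "MBD", "MZS", "MZD"),
}

SUBDOMAINS = tuple(DEFAULT_INVENTORIES)

_FORBIDDEN = {"mG", "fG"}  # underspecified sibling covers, never inventory


def subdomain_kin_types(
    subdomain: str,
    inventories: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[KinType, ...]:
    """The kin-type inventory defining a subdomain.

    ``inventories`` overrides the package defaults (the sibling inventory
    is fixed by definition and should not normally be overridden).  Codes
    that are underspecified covers of the inventory (mG, fG) are rejected.
    """
    table = DEFAULT_INVENTORIES if inventories is None else inventories
    if subdomain not in table:
        raise ValueError(
            f"unknown kinship subdomain {subdomain!r}; expected one of "
            f"{sorted(table)}"
        )
    codes = tuple(table[subdomain])
    bad = _FORBIDDEN.intersection(codes)
    if bad:
        raise ValueError(
            f"inventory for {subdomain!r} contains underspecified cover "
            f"codes {sorted(bad)}; inventories must contain proper subsets "
            "only"
        )
    if len(set(codes)) != len(codes):
        raise ValueError(f"inventory for {subdomain!r} has duplicate codes")
    return tuple(parse_kin_code(c) for c in codes)


@dataclass(frozen=True)
class TermExtension:
    """One kinship term and the set of kin types it can denote."""

    language: str
    glottocode: str
    term: str
    extension: frozenset[KinType]


def extract_category_system(
    terms: Iterable[TermExtension],
    subdomain: str,
    inventories: Optional[Mapping[str, Sequence[str]]] = None,
) -> int:
    """Category-system size for one language over one subdomain.

    Each term's extension is restricted to the subdomain inventory, terms
    left with empty extensions are dropped, and the size is the number of
    *distinct* restricted extensions.  Raises
    :class:`EmptySubdomainError` when no term touches the subdomain at
    all, so an absent domain is reported rather than silently counted as
    zero.
    """
    terms = list(terms)
    languages = {t.language for t in terms}
    if len(languages) > 1:
        raise ValueError(
            f"term table mixes languages {sorted(languages)}; extract one "
            "language at a time"
        )
    inventory = frozenset(subdomain_kin_types(subdomain, inventories))
    extensions = set()
    for t in terms:
        restricted = frozenset(t.extension) & inventory
        if restricted:
            extensions.add(restricted)
    if not extensions:
        raise EmptySubdomainError(
            f"language {next(iter(languages), '?')!r} has no terms covering "
            f"subdomain {subdomain!r}"
        )
    return len(extensions)


def read_kin_table(path) -> list[TermExtension]:
    """Read a kin-term CSV (columns language, glottocode, term, kin_type;
    one row per term × kin-type pair) into grouped term extensions."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"language", "glottocode", "term", "kin_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"kin-term table missing columns {sorted(missing)}")
    out: dict[tuple[str, str, str], set[KinType]] = {}
    for row in df.itertuples(index=False):
        key = (row.language, row.glottocode, row.term)
        out.setdefault(key, set()).add(parse_kin_code(row.kin_type))
    return [
        TermExtension(language=lang, glottocode=glot, term=term,
                      extension=frozenset(ext))
        for (lang, glot, term), ext in out.items()
    ]


def sibling_feature_bijection() -> dict[tuple[int, int], KinType]:
    """Bijection between the 2x2 binary-feature space and the four
    age × sex sibling kin types (speaker sex unspecified).

    Feature 0 is relative age (0 = elder, 1 = younger), feature 1 is
    referent sex (0 = male, 1 = female): (0, 0) -> eB, (0, 1) -> eZ,
    (1, 0) -> yB, (1, 1) -> yZ.  This is the sense in which the sibling
    subdomain instantiates the two-feature structure.
    """
    codes = {(0, 0): "eB", (0, 1): "eZ", (1, 0): "yB", (1, 1): "yZ"}
    return {bits: parse_kin_code(code) for bits, code in codes.items()}
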