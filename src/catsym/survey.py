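"""Cross-linguistic system records: I/O, curation rules, parity summaries.

A :class:`SystemRecord` is one attested category system for one language in
one domain (day names, seasons, kin subdomains, ...).  The curation rules
implemented here mirror standard typological-survey practice:

* one record per glottocode, with conservative tie-breaking — when two
  records for the same glottocode disagree in parity, the record whose
  parity *contradicts* the hypothesised preference is kept;
* only the largest system per language for domains where sources record
  nested systems (e.g. sections vs subsections in Australian social
  classification);
* color-naming system size from a participant × chip × term matrix: a term
  counts when at least a threshold fraction of participants (default 60%)
  used it for at least one chip.

Records with a missing glottocode are retained but flagged, since they
cannot enter a family-grouped regression.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "SystemRecord",
    "ParitySummary",
    "read_system_records",
    "write_system_records",
    "dedupe_by_glottocode",
    "largest_per_language",
    "count_color_terms",
    "parity_summary",
]

REQUIRED_COLUMNS = ("language", "glottocode", "family", "domain", "size")


@dataclass(frozen=True)
class SystemRecord:
    """One language × domain category system."""

    language: str
    glottocode: str
    family: str
    domain: str
    size: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(
                f"system size must be >= 1, got {self.size} for "
                f"{self.language!r}"
            )

    @property
    def parity(self) -> str:
        return "even" if self.size % 2 == 0 else "odd"

    @property
    def excluded_from_regression(self) -> bool:
        """Records without a glottocode cannot be grouped into a family."""
        return not self.glottocode


@dataclass(frozen=True)
class ParitySummary:
    """Size histogram plus odd/even counts for a set of records."""

    size_histogram: dict[int, int]
    n_odd: int
    n_even: int
    all_powers_of_two: bool

    @property
    def n(self) -> int:
        return self.n_odd + self.n_even

    def to_dict(self) -> dict:
        return {
            "size_histogram": {
                str(k): v for k, v in sorted(self.size_histogram.items())
            },
            "n_odd": self.n_odd,
            "n_even": self.n_even,
            "all_powers_of_two": self.all_powers_of_two,
        }


def read_system_records(path) -> list[SystemRecord]:
    """Read a systems CSV (UTF-8, comma-separated, header required, columns
    language, glottocode, family, domain, size[, source]).

    Sizes must be positive integers; a malformed size fails naming the row.
    Rows with an empty glottocode are kept (they still enter size
    summaries) but are flagged as excluded from regression.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"systems table missing columns {sorted(missing)}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        raw = str(row.size).strip()
        try:
            size = int(raw)
        except ValueError:
            raise ValueError(
                f"row {pos}: size {raw!r} is not an integer "
                f"(language {row.language!r})"
            ) from None
        records.append(
            SystemRecord(
                language=row.language,
                glottocode=row.glottocode.strip(),
                family=row.family,
                domain=row.domain,
                size=size,
                source=getattr(row, "source", ""),
            )
        )
    return records


def write_system_records(records: Sequence[SystemRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "language": r.language,
                "glottocode": r.glottocode,
                "family": r.family,
                "domain": r.domain,
                "size": r.size,
                "source": r.source,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def dedupe_by_glottocode(
    records: Sequence[SystemRecord], predicted_parity: str = "none"
) -> list[SystemRecord]:
    """Keep one record per glottocode.

    When duplicate records agree in parity the first is kept.  When they
    disagree, the record whose parity contradicts ``predicted_parity`` is
    kept — conservative with respect to the hypothesis being tested.  With
    ``predicted_parity="none"`` the first record is kept and a warning
    notes the unresolved conflict.  Records without a glottocode cannot be
    matched and pass through unchanged.
    """
    if predicted_parity not in ("odd", "even", "none"):
        raise ValueError(
            f"predicted_parity must be odd, even or none, got "
            f"{predicted_parity!r}"
        )
    groups: dict[str, list[SystemRecord]] = {}
    order: list[tuple[str, SystemRecord]] = []
    for r in records:
        if not r.glottocode:
            order.append(("", r))
            continue
        if r.glottocode not in groups:
            order.append((r.glottocode, r))
            groups[r.glottocode] = []
        groups[r.glottocode].append(r)
    out = []
    for glottocode, first in order:
        if not glottocode:
            out.append(first)
            continue
        dups = groups[glottocode]
        parities = {r.parity for r in dups}
        if len(parities) == 1:
            out.append(dups[0])
        elif predicted_parity == "none":
            warnings.warn(
                f"glottocode {glottocode}: duplicate records with conflicting "
                "parity and no predicted parity; keeping the first",
                stacklevel=2,
            )
            out.append(dups[0])
        else:
            contradicting = [r for r in dups if r.parity != predicted_parity]
            out.append(contradicting[0])
    return out


def largest_per_language(records: Sequence[SystemRecord]) -> list[SystemRecord]:
    """Keep only the largest system per language (ties keep the first)."""
    best: dict[str, SystemRecord] = {}
    order: list[str] = []
    for r in records:
        if r.language not in best:
            best[r.language] = r
            order.append(r.language)
        elif r.size > best[r.language].size:
            best[r.language] = r
    return [best[lang] for lang in order]


def count_color_terms(naming, threshold: float = 0.6) -> int:
    """Color-naming system size under the consensus rule.

    ``naming`` is a DataFrame (or CSV path) with columns participant,
    chip, term; each (participant, chip) pair may carry at most one term.
    A term is counted when, for at least one chip, the fraction of the
    survey's participants who used it for that chip is >= ``threshold``
    (boundary inclusive; default 0.6).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not isinstance(naming, pd.DataFrame):
        naming = pd.read_csv(naming, dtype=str)
    required = {"participant", "chip", "term"}
    missing = required - set(naming.columns)
    if missing:
        raise ValueError(f"color table missing columns {sorted(missing)}")
    if naming.empty:
        raise ValueError("color-naming table is empty")
    if naming.duplicated(["participant", "chip"]).any():
        raise ValueError(
            "a (participant, chip) pair carries more than one term"
        )
    n_participants = naming["participant"].nunique()
    counts = (
        naming.groupby(["chip", "term"])["participant"].nunique()
        / n_participants
    )
    peak = counts.groupby("term").max()
    return int((peak >= threshold).sum())


def parity_summary(records: Sequence[SystemRecord]) -> ParitySummary:
    """Histogram of system sizes with odd/even counts.

    ``all_powers_of_two`` is true when every size is a power of two
    (1 = 2**0 counts as one; the substantive claim in practice concerns
    sizes 2, 4 and 8)."""
    if not records:
        raise ValueError("cannot summarise an empty record set")
    hist = Counter(r.size for r in records)
    n_even = sum(1 for r in records if r.size % 2 == 0)
    powers = all(s & (s - 1) == 0 for s in hist)
    return ParitySummary(
        size_histogram=dict(hist),
        n_odd=len(records) - n_even,
        n_even=n_even,
        all_powers_of_two=powers,
    )
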