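"""Synthetic cross-linguistic surveys, kin-term tables and color matrices.

The survey generator emulates the statistical shape the parity analysis
assumes: languages nested in families, a domain-level parity preference
theta_even on the probability scale with family- (and optionally
language-) level deviations on the logit scale, and sawtooth size
distributions whose probability mass alternates between adjacent odd and
even sizes.  It is the package's stand-in for archived field surveys; it
reproduces their statistical structure, not their values.

Every generator is a pure function of its seed: the same configuration and
seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .kinship import KinType, TermExtension
from .survey import SystemRecord

__all__ = [
    "SurveySimConfig",
    "KinSimConfig",
    "simulate_survey",
    "simulate_sizes",
    "simulate_kin_table",
    "simulate_color_table",
    "SIZE_PRESETS",
]

#: Named sawtooth weight maps, loosely shaped on the qualitative size
#: profiles of real surveys (day-name systems cluster at 5 and 7; season
#: and cardinal systems at 4; sibling systems at 2 and 4).  They are test
#: fixtures with realistic shape, not estimates of any archived data.
SIZE_PRESETS: dict[str, dict[str, dict[int, float]]] = {
    "day-names": {
        "odd": {3: 0.20, 5: 0.45, 7: 0.25, 9: 0.10},
        "even": {2: 0.25, 4: 0.40, 6: 0.25, 8: 0.10},
    },
    "seasons": {
        "odd": {3: 0.55, 5: 0.35, 7: 0.10},
        "even": {2: 0.25, 4: 0.55, 6: 0.15, 8: 0.05},
    },
    "kinship-siblings": {
        "odd": {3: 0.60, 5: 0.30, 7: 0.10},
        "even": {2: 0.35, 4: 0.40, 6: 0.15, 8: 0.10},
    },
}

#: Preset domain-level parity preferences paired with the weight maps.
THETA_PRESETS = {"day-names": 0.2, "seasons": 0.85, "kinship-siblings": 0.9}


def _validate_weights(weights: Mapping[int, float], parity: str) -> None:
    if not weights:
        raise ValueError(f"empty {parity} size-weight map")
    want = 0 if parity == "even" else 1
    bad = [s for s in weights if s % 2 != want or s < 1]
    if bad:
        raise ValueError(
            f"{parity} size-weight map contains wrong-parity or invalid "
            f"sizes {sorted(bad)}"
        )
    total = float(sum(weights.values()))
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(
            f"{parity} size weights must sum to 1, got {total}"
        )


@dataclass(frozen=True)
class SurveySimConfig:
    """Generative settings for a synthetic survey.

    ``theta_even`` is the domain's parity preference for a typical family;
    ``sigma_family``/``sigma_language`` are logit-scale deviation SDs;
    ``duplicates_per_language`` emulates multiple sources per language.
    Defaults give a medium-sized survey (30 families x 5 languages) with
    moderate family clustering, the regime the estimator is designed for.
    """

    n_families: int = 30
    languages_per_family: int = 5
    theta_even: float = 0.7
    sigma_family: float = 0.5
    sigma_language: float = 0.0
    even_size_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(SIZE_PRESETS["seasons"]["even"])
    )
    odd_size_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(SIZE_PRESETS["seasons"]["odd"])
    )
    duplicates_per_language: int = 1
    domain: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta_even < 1:
            raise ValueError("theta_even must be in (0, 1)")
        if self.n_families < 1 or self.languages_per_family < 1:
            raise ValueError("need >= 1 family and >= 1 language per family")
        if self.sigma_family < 0 or self.sigma_language < 0:
            raise ValueError("deviation SDs must be nonnegative")
        if self.duplicates_per_language < 1:
            raise ValueError("duplicates_per_language must be >= 1")
        _validate_weights(self.even_size_weights, "even")
        _validate_weights(self.odd_size_weights, "odd")

    @classmethod
    def preset(cls, name: str, seed: int = 0, **overrides) -> "SurveySimConfig":
        if name not in SIZE_PRESETS:
            raise ValueError(
                f"unknown preset {name!r}; expected one of "
                f"{sorted(SIZE_PRESETS)}"
            )
        kwargs = dict(
            theta_even=THETA_PRESETS[name],
            even_size_weights=dict(SIZE_PRESETS[name]["even"]),
            odd_size_weights=dict(SIZE_PRESETS[name]["odd"]),
            domain=name,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def simulate_sizes(
    parity: str, weights: Mapping[int, float], rng: np.random.Generator
) -> int:
    """Draw one system size of the requested parity from a weight map."""
    if parity not in ("odd", "even"):
        raise ValueError(f"parity must be odd or even, got {parity!r}")
    _validate_weights(weights, parity)
    sizes = sorted(weights)
    probs = np.array([weights[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(sizes, p=probs))


def simulate_survey(config: SurveySimConfig) -> list[SystemRecord]:
    """Generate system records under the hierarchical parity model.

    Each language's probability of an even system is
    logistic(logit(theta_even) + family deviation + language deviation);
    each record (one per source) draws its parity from that probability
    and its size from the matching weight map.
    """
    rng = np.random.default_rng(config.seed)
    base = float(logit(config.theta_even))
    records = []
    for f in range(config.n_families):
        fam_dev = config.sigma_family * rng.standard_normal()
        family = f"family{f:03d}"
        for l in range(config.languages_per_family):
            lang_dev = config.sigma_language * rng.standard_normal()
            p_even = float(expit(base + fam_dev + lang_dev))
            language = f"lang{f:03d}_{l:02d}"
            glottocode = f"{language}1234"
            for d in range(config.duplicates_per_language):
                parity = "even" if rng.random() < p_even else "odd"
                weights = (
                    config.even_size_weights
                    if parity == "even"
                    else config.odd_size_weights
                )
                records.append(
                    SystemRecord(
                        language=language,
                        glottocode=glottocode,
                        family=family,
                        domain=config.domain,
                        size=simulate_sizes(parity, weights, rng),
                        source=f"source{d}",
                    )
                )
    return records


@dataclass(frozen=True)
class KinSimConfig:
    """A target kin category system: a partition of an inventory into
    blocks, each realised by ``n_synonyms`` distinct terms."""

    target_system: tuple[frozenset[KinType], ...]
    n_synonyms: int = 1
    language: str = "synthlang"
    glottocode: str = "synt1234"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_synonyms < 1:
            raise ValueError("n_synonyms must be >= 1")
        seen: set[KinType] = set()
        for block in self.target_system:
            if not block:
                raise ValueError("target system blocks must be nonempty")
            if seen & block:
                raise ValueError("target system blocks must be disjoint")
            seen |= block


def simulate_kin_table(config: KinSimConfig) -> list[TermExtension]:
    """Emit a term-extension table realising the target partition: block i
    gets terms term<i>_<j>, each with the whole block as extension.  Row
    order is shuffled by the seed; extraction recovers exactly the number
    of blocks."""
    rng = np.random.default_rng(config.seed)
    rows = [
        TermExtension(
            language=config.language,
            glottocode=config.glottocode,
            term=f"term{i}_{j}",
            extension=frozenset(block),
        )
        for i, block in enumerate(config.target_system)
        for j in range(config.n_synonyms)
    ]
    rng.shuffle(rows)
    return rows


def simulate_color_table(
    n_participants: int,
    n_chips: int,
    n_consensus_terms: int,
    seed: int = 0,
    threshold: float = 0.6,
):
    """Participant × chip × term matrix with exactly ``n_consensus_terms``
    terms that reach the consensus threshold on some chip.

    Consensus terms each own one chip where every participant uses them;
    the remaining chips receive idiosyncratic low-agreement labels spread
    so that no non-consensus term reaches the threshold anywhere.
    """
    import pandas as pd

    if n_consensus_terms > n_chips:
        raise ValueError("need at least one chip per consensus term")
    if n_participants < 2:
        raise ValueError("need >= 2 participants")
    rng = np.random.default_rng(seed)
    max_share = max(1, int(np.ceil(threshold * n_participants)) - 1)
    n_noise_terms = max(
        n_consensus_terms + 1,
        int(np.ceil(n_participants / max_share)) + n_consensus_terms,
    )
    rows = []
    for chip in range(n_chips):
        if chip < n_consensus_terms:
            labels = [f"big{chip}"] * n_participants
        else:
            # cycle noise terms so none exceeds max_share on this chip
            noise = [f"noise{t}" for t in range(n_noise_terms)]
            labels = [
                noise[(p // max_share) % n_noise_terms]
                for p in range(n_participants)
            ]
        order = rng.permutation(n_participants)
        for p in range(n_participants):
            rows.append(
                {
                    "participant": f"p{order[p]:03d}",
                    "chip": f"c{chip:03d}",
                    "term": labels[p],
                }
            )
    return pd.DataFrame(rows)
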