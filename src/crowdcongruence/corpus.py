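"""Domain containers for the crowdsourced hospital-quality analysis.

The objects here mirror the units of the study design: a registry of
pediatric clinics with their official antibiotic-prescription rates, an
alias dictionary mapping canonical clinic names to the surface forms users
write in forum messages, the forum content itself (threads and messages),
the mention records produced by extraction, and the ground truth a
synthetic corpus carries alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SENTIMENTS = ("positive", "neutral", "negative", "ambiguous", "unlabeled")


@dataclass(frozen=True)
class Hospital:
    """A pediatric clinic in the official registry.

    ``antibiotic_rate`` is the official quality index: antibiotic
    prescriptions divided by visits, in [0, 1]; lower is better.
    """

    hospital_id: str
    canonical_name: str
    district_id: str
    antibiotic_rate: float
    n_doctors: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.antibiotic_rate <= 1.0:
            raise ValueError(
                f"antibiotic_rate must be in [0,1], got {self.antibiotic_rate!r} "
                f"for {self.hospital_id}"
            )
        if self.n_doctors < 1:
            raise ValueError(f"n_doctors must be >= 1 for {self.hospital_id}")


@dataclass
class AliasDictionary:
    """Canonical clinic name -> set of surface forms.

    Every canonical name maps to a set that contains the name itself;
    ``hospital_ids`` resolves canonical names back to registry identifiers.
    """

    entries: dict[str, set[str]]
    hospital_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for canonical, forms in self.entries.items():
            forms.add(canonical)

    @property
    def n_hospitals(self) -> int:
        return len(self.entries)

    def mean_alias_count(self, include_identity: bool = False) -> float:
        """Mean number of surface forms per clinic (identity excluded by
        default, matching the 'similar expressions' convention)."""
        if not self.entries:
            return 0.0
        extra = 0 if include_identity else -1
        return sum(len(v) + extra for v in self.entries.values()) / len(self.entries)

    def all_surfaces(self) -> set[str]:
        out: set[str] = set()
        for forms in self.entries.values():
            out |= forms
        return out


@dataclass(frozen=True)
class Thread:
    thread_id: str
    district_id: str


@dataclass(frozen=True)
class Message:
    message_id: str
    thread_id: str
    district_id: str
    is_reply: bool
    text: str
    sentiment: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.sentiment not in SENTIMENTS:
            raise ValueError(
                f"unknown sentiment {self.sentiment!r} on message {self.message_id}"
            )


@dataclass(frozen=True)
class MentionRecord:
    """A resolved hospital mention: the surface form as matched in the
    message, the registry hospital it normalizes to, and the edit distance
    to the matched alias.  Sentiment is inherited from the message."""

    message_id: str
    hospital_id: str
    surface_form: str
    distance: int
    sentiment: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass
class GroundTruth:
    """What a synthetic corpus knows about itself.

    ``mentions`` maps message_id to the gold set of mentioned hospital ids
    (messages without mentions may be absent).  ``perceived_ranking`` is the
    per-district hospital ordering by perceived quality (best first), the
    ordering the crowd signal is built from; ``noise_sd`` is the per-district
    standard deviation of the perceived-quality noise.
    """

    mentions: dict[str, set[str]]
    perceived_ranking: dict[str, list[str]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)

    def gold_for(self, message_id: str) -> set[str]:
        return self.mentions.get(message_id, set())
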