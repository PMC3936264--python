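"""Per-district crowd and government quality rankings.

The crowd ranking orders clinics by how often they are mentioned
(positively or neutrally) in a district's forum messages, most-mentioned
first.  The government ranking orders the same clinics by official
antibiotic prescription rate, lowest first (low prescribing = high
quality).  Both use average ranks on ties, and congruence is computed only
over the clinics that received at least one retained mention.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .corpus import Hospital, MentionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RankingPair",
    "count_mentions",
    "crowd_ranking",
    "government_ranking",
    "align_rankings",
    "build_ranking_pairs",
]


@dataclass
class RankingPair:
    """Aligned crowd and government rank vectors over a district's
    commonly rankable clinics (those with at least one retained mention).

    Both rank vectors use the average-rank convention on ties, so each
    sums to n(n+1)/2.  Districts with fewer than the configured minimum of
    rankable clinics are flagged ``excluded`` rather than dropped silently.
    """

    district_id: str
    hospital_ids: list[str]
    crowd_rank: np.ndarray
    gov_rank: np.ndarray
    n: int
    excluded: bool = False
    mention_counts: dict[str, int] = field(default_factory=dict)


def count_mentions(
    mentions: Iterable[MentionRecord], registry: Sequence[Hospital]
) -> pd.DataFrame:
    """Mention frequency per (district, hospital).

    Callers pass sentiment-filtered mentions; clinics with zero mentions do
    not appear.  Districts are taken from the registry entry of each
    mentioned hospital.
    """
    district_of = {h.hospital_id: h.district_id for h in registry}
    counts: Counter[tuple[str, str]] = Counter()
    for m in mentions:
        if m.hospital_id not in district_of:
            raise KeyError(f"mention of unknown hospital {m.hospital_id!r}")
        counts[(district_of[m.hospital_id], m.hospital_id)] += 1
    rows = [
        {"district_id": d, "hospital_id": h, "mentions": c}
        for (d, h), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["district_id", "hospital_id", "mentions"])


def crowd_ranking(frequencies: pd.Series) -> pd.Series:
    """Ranks from mention frequencies: highest frequency -> rank 1,
    average ranks on ties.  Index (hospital ids) is preserved."""
    if len(frequencies) == 0:
        raise ValueError("cannot rank an empty frequency table")
    ranks = rankdata(-frequencies.to_numpy(dtype=float), method="average")
    return pd.Series(ranks, index=frequencies.index, name="crowd_rank")


def government_ranking(
    registry: Sequence[Hospital],
    district_id: str,
    restrict_to: Iterable[str] | None = None,
) -> pd.Series:
    """Official ranks within a district: lowest antibiotic rate -> rank 1,
    average ranks on ties, optionally restricted to a subset of the
    district's clinics (the mentioned set)."""
    in_district = {h.hospital_id: h for h in registry if h.district_id == district_id}
    if restrict_to is None:
        ids = sorted(in_district)
    else:
        ids = sorted(set(restrict_to))
        unknown = [i for i in ids if i not in in_district]
        if unknown:
            raise KeyError(
                f"hospitals {unknown} not in registry for district {district_id}"
            )
    if not ids:
        raise ValueError(f"no hospitals to rank in district {district_id}")
    rates = np.array([in_district[i].antibiotic_rate for i in ids])
    ranks = rankdata(rates, method="average")
    return pd.Series(ranks, index=pd.Index(ids, name="hospital_id"), name="gov_rank")


def align_rankings(
    crowd: pd.Series,
    gov: pd.Series,
    district_id: str,
    min_n: int = 2,
) -> RankingPair:
    """Build a :class:`RankingPair` over the intersection of the two
    rankings' hospital sets, re-ranking both within the intersection.

    An empty or sub-minimum intersection yields an ``excluded`` pair
    (mirroring the exclusion of districts with too little online coverage),
    not an error.
    """
    common = sorted(set(crowd.index) & set(gov.index))
    if len(common) < min_n:
        logger.info(
            "district %s excluded: %d commonly rankable clinics (minimum %d)",
            district_id,
            len(common),
            min_n,
        )
        return RankingPair(
            district_id=district_id,
            hospital_ids=common,
            crowd_rank=np.array([]),
            gov_rank=np.array([]),
            n=len(common),
            excluded=True,
        )
    crowd_sub = rankdata(crowd.loc[common].to_numpy(), method="average")
    gov_sub = rankdata(gov.loc[common].to_numpy(), method="average")
    return RankingPair(
        district_id=district_id,
        hospital_ids=common,
        crowd_rank=crowd_sub,
        gov_rank=gov_sub,
        n=len(common),
    )


def build_ranking_pairs(
    frequency_table: pd.DataFrame,
    registry: Sequence[Hospital],
    min_n: int = 2,
) -> tuple[list[RankingPair], list[str]]:
    """One aligned ranking pair per district with any mentions.

    Mentions of hospitals absent from the registry were already rejected in
    :func:`count_mentions`; districts falling below ``min_n`` commonly
    rankable clinics are returned in the excluded list.
    """
    pairs: list[RankingPair] = []
    excluded: list[str] = []
    for district_id, grp in frequency_table.groupby("district_id", sort=True):
        freq = grp.set_index("hospital_id")["mentions"]
        crowd = crowd_ranking(freq)
        gov = government_ranking(registry, str(district_id), restrict_to=freq.index)
        pair = align_rankings(crowd, gov, str(district_id), min_n=min_n)
        pair.mention_counts = freq.to_dict()
        pairs.append(pair)
        if pair.excluded:
            excluded.append(str(district_id))
    return pairs, excluded


def ranking_frame(pairs: Sequence[RankingPair]) -> pd.DataFrame:
    """Long-format per-clinic table (district, hospital, mentions,
    crowd_rank, gov_rank, n) for the non-excluded pairs."""
    rows = []
    for p in pairs:
        if p.excluded:
            continue
        for i, hid in enumerate(p.hospital_ids):
            rows.append(
                {
                    "district_id": p.district_id,
                    "hospital_id": hid,
                    "mentions": p.mention_counts.get(hid, 0),
                    "crowd_rank": p.crowd_rank[i],
                    "gov_rank": p.gov_rank[i],
                    "n": p.n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["district_id", "hospital_id", "mentions", "crowd_rank", "gov_rank", "n"],
    )
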