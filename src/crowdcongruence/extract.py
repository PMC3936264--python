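"""Preprocessing and dictionary-based hospital-name extraction.

Forum users rarely write a clinic's registry name: acronyms, truncations
and misspellings dominate.  Extraction therefore resolves candidate text
spans through a stepwise expression normalization: (1) exact canonical
match, (2) exact alias match, (3) minimum Levenshtein-distance alias match
subject to a per-alias threshold.  Short aliases (acronyms) must match
exactly; longer aliases tolerate proportionally more edits.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .corpus import AliasDictionary, GroundTruth, MentionRecord, Message, Thread
from .distance import levenshtein

logger = logging.getLogger(__name__)

__all__ = [
    "EvalMetrics",
    "strip_markup",
    "filter_candidates",
    "default_threshold",
    "normalize_expression",
    "AliasIndex",
    "extract_mentions",
    "filter_sentiment",
    "evaluate_extraction",
]

#: sentiment labels retained by the crowd-signal filter (ambiguous
#: messages, where positive and negative coexist, count as neutral)
RETAINED_SENTIMENTS = frozenset({"positive", "neutral", "ambiguous"})

DEFAULT_DOMAIN_KEYWORDS = frozenset({"pediatric"})
DEFAULT_REQUEST_KEYWORDS = frozenset({"recommendation"})


@dataclass(frozen=True)
class EvalMetrics:
    """Extraction accuracy on a message sample.

    f1 is the harmonic mean 2PR/(P+R), with the convention that an
    undefined precision (no predictions) is 0.
    """

    precision: float
    recall: float
    f1: float
    n_messages: int = 0
    n_predicted: int = 0
    n_gold: int = 0

    def __post_init__(self) -> None:
        for name in ("precision", "recall", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


def strip_markup(raw: str) -> str:
    """Visible text of an HTML fragment; plain text passes through
    unchanged.  Script and style content, comments, tags and attributes
    are discarded; markup need not be well formed."""
    if "<" not in raw:
        return raw
    import lxml.html

    try:
        doc = lxml.html.fromstring(raw)
    except Exception:  # pragma: no cover - lxml is extremely lenient
        return raw
    for el in doc.iter("script", "style"):
        parent = el.getparent()
        if parent is not None:
            parent.remove(el)
    text = doc.text_content()
    return " ".join(text.split())


def filter_candidates(
    threads: Sequence[Thread] | None,
    messages: Sequence[Message],
    domain_keywords: Iterable[str] = DEFAULT_DOMAIN_KEYWORDS,
    request_keywords: Iterable[str] = DEFAULT_REQUEST_KEYWORDS,
) -> list[Message]:
    """Reply messages from threads whose root is a hospital-recommendation
    request.

    A thread qualifies when its root message contains (case-insensitively)
    at least one domain keyword and one request keyword.  ``threads``, when
    given, restricts attention to those thread ids.
    """
    domain = [k.casefold() for k in domain_keywords]
    request = [k.casefold() for k in request_keywords]
    allowed = None if threads is None else {t.thread_id for t in threads}
    qualifying: set[str] = set()
    for m in messages:
        if m.is_reply:
            continue
        if allowed is not None and m.thread_id not in allowed:
            continue
        text = m.text.casefold()
        if any(k in text for k in domain) and any(k in text for k in request):
            qualifying.add(m.thread_id)
    return [m for m in messages if m.is_reply and m.thread_id in qualifying]


def default_threshold(alias: str) -> int:
    """Maximum accepted edit distance for an alias: a quarter of its
    length, rounded down.  Aliases of three characters or fewer (acronyms)
    must match exactly."""
    return len(alias) // 4


def _make_threshold(threshold: int | Callable[[str], int] | None) -> Callable[[str], int]:
    if threshold is None:
        return default_threshold
    if callable(threshold):
        return threshold
    fixed = int(threshold)
    if fixed < 0:
        raise ValueError("threshold must be non-negative")
    return lambda alias: fixed


def _normalize_surface(surface: str) -> str:
    return " ".join(surface.split()).casefold()


class AliasIndex:
    """Matching structure over an alias dictionary.

    Exact lookups go through hash maps; fuzzy lookups scan aliases whose
    token count and length are compatible with the span, pruned by a
    character-count lower bound before the banded dynamic program runs.
    Fuzzy matches respect whitespace token boundaries (a two-token span
    can only fuzzily match a two-token alias), since token segmentation is
    reliable here and ignoring it invites filler-word false positives.
    Lookups are memoized, which matters because forum filler vocabulary
    repeats heavily.
    """

    def __init__(
        self,
        dictionary: AliasDictionary,
        threshold: int | Callable[[str], int] | None = None,
    ):
        if not dictionary.entries:
            raise ValueError("alias dictionary is empty")
        self.threshold = _make_threshold(threshold)
        self._canonical_exact: dict[str, tuple[str, str]] = {}
        self._alias_exact: dict[str, tuple[str, str, str]] = {}
        # fuzzy candidates: (norm_alias, allowed, canonical)
        fuzzy: list[tuple[str, int, str]] = []
        self._cache: dict[str, tuple[str, int] | tuple[None, None]] = {}
        self.max_alias_tokens = 1
        for canonical in sorted(dictionary.entries):
            hid = dictionary.hospital_ids.get(canonical, canonical)
            norm_canon = _normalize_surface(canonical)
            self._canonical_exact.setdefault(norm_canon, (canonical, hid))
            for alias in sorted(dictionary.entries[canonical]):
                norm = _normalize_surface(alias)
                if not norm:
                    continue
                self.max_alias_tokens = max(self.max_alias_tokens, norm.count(" ") + 1)
                prev = self._alias_exact.get(norm)
                # same surface listed for two clinics: keep the
                # lexicographically smallest canonical name
                if prev is None or canonical < prev[0]:
                    self._alias_exact[norm] = (canonical, hid, norm)
                allowed = self.threshold(norm)
                if allowed > 0:
                    fuzzy.append((norm, allowed, canonical))
        self._build_fuzzy_arrays(fuzzy)

    def _build_fuzzy_arrays(self, fuzzy: list[tuple[str, int, str]]) -> None:
        """Character-count vectors over all fuzzy-matchable aliases, used
        to prune the alias scan in one vectorized pass: half the L1
        distance between count vectors (and the length gap) lower-bounds
        the edit distance."""
        self._fuzzy = fuzzy
        alphabet = sorted({ch for alias, _, _ in fuzzy for ch in alias})
        self._char_col = {ch: i for i, ch in enumerate(alphabet)}
        n_cols = len(alphabet) + 1  # final column pools unseen characters
        mat = np.zeros((len(fuzzy), n_cols), dtype=np.int16)
        for row, (alias, _, _) in enumerate(fuzzy):
            for ch in alias:
                mat[row, self._char_col[ch]] += 1
        self._fuzzy_mat = mat
        self._fuzzy_len = np.array([len(a) for a, _, _ in fuzzy], dtype=np.int16)
        self._fuzzy_allowed = np.array([t for _, t, _ in fuzzy], dtype=np.int16)
        # fuzzy matches respect token boundaries: a span only matches
        # aliases with the same number of whitespace tokens
        self._fuzzy_tokens = np.array(
            [a.count(" ") + 1 for a, _, _ in fuzzy], dtype=np.int16
        )

    def normalize(
        self, surface: str, exact_only: bool = False
    ) -> tuple[str | None, int | None]:
        """Stepwise normalization of one surface form.

        Returns ``(canonical_name, distance)`` or ``(None, None)`` when no
        alias lies within its threshold.  Ties at the minimal distance
        prefer the longer alias (more specific), then the lexicographically
        smallest canonical name.
        """
        norm = _normalize_surface(surface)
        if not norm:
            return None, None
        exact = self._lookup_exact(norm)
        if exact is not None or exact_only:
            return exact if exact is not None else (None, None)
        hit = self._cache.get(norm)
        if hit is not None:
            return hit[0], hit[1]
        result = self._lookup_fuzzy(norm)
        self._cache[norm] = result
        return result

    def resolve(
        self, surface: str, exact_only: bool = False
    ) -> tuple[str | None, str | None, int | None]:
        """Like :meth:`normalize` but also returns the hospital id."""
        canonical, dist = self.normalize(surface, exact_only=exact_only)
        if canonical is None:
            return None, None, None
        hid = self._canonical_exact[_normalize_surface(canonical)][1]
        return canonical, hid, dist

    def _lookup_exact(self, norm: str) -> tuple[str, int] | None:
        exact = self._canonical_exact.get(norm)
        if exact is not None:
            return exact[0], 0
        alias_hit = self._alias_exact.get(norm)
        if alias_hit is not None:
            return alias_hit[0], 0
        return None

    def _lookup_fuzzy(self, norm: str) -> tuple[str, int] | tuple[None, None]:
        if not self._fuzzy:
            return None, None
        vec = np.zeros(self._fuzzy_mat.shape[1], dtype=np.int16)
        other = self._fuzzy_mat.shape[1] - 1
        for ch in norm:
            vec[self._char_col.get(ch, other)] += 1
        l1 = np.abs(self._fuzzy_mat - vec).sum(axis=1)
        gap = np.abs(self._fuzzy_len - len(norm))
        candidates = np.nonzero(
            (self._fuzzy_tokens == norm.count(" ") + 1)
            & (gap <= self._fuzzy_allowed)
            & ((l1 + 1) // 2 <= self._fuzzy_allowed)
        )[0]
        best: tuple[int, int, str] | None = None  # (distance, -alias_len, canonical)
        for idx in candidates:
            alias, allowed, canonical = self._fuzzy[int(idx)]
            d = levenshtein(norm, alias, limit=allowed)
            if d > allowed:
                continue
            key = (d, -len(alias), canonical)
            if best is None or key < best:
                best = key
        if best is None:
            return None, None
        return best[2], best[0]


def normalize_expression(
    surface: str,
    dictionary: AliasDictionary | AliasIndex,
    threshold: int | Callable[[str], int] | None = None,
) -> tuple[str | None, int | None]:
    """Resolve one surface form to a canonical clinic name.

    Convenience wrapper around :class:`AliasIndex`; callers processing many
    spans should build the index once.
    """
    index = (
        dictionary
        if isinstance(dictionary, AliasIndex)
        else AliasIndex(dictionary, threshold)
    )
    return index.normalize(surface)


_PUNCT = string.punctuation


def _spans(tokens: list[str], max_n: int) -> Iterable[tuple[int, int, str]]:
    for i in range(len(tokens)):
        for n in range(1, max_n + 1):
            if i + n > len(tokens):
                break
            yield i, i + n, " ".join(tokens[i : i + n])


def extract_mentions(
    candidates: Sequence[Message],
    dictionary: AliasDictionary | AliasIndex,
    threshold: int | Callable[[str], int] | None = None,
    max_ngram: int = 5,
    dedupe: bool = True,
) -> list[MentionRecord]:
    """Dictionary-based mention extraction over candidate messages.

    Messages are whitespace-tokenized and all token n-grams up to
    ``max_ngram`` are normalized (fuzzy matching is only attempted for
    spans no longer, in tokens, than the longest alias).  With ``dedupe``
    (default) at most one record per (message, hospital) is emitted,
    carrying the minimal distance; without it, overlapping matched spans
    for the same hospital are merged and each merged occurrence yields a
    record.
    """
    index = (
        dictionary
        if isinstance(dictionary, AliasIndex)
        else AliasIndex(dictionary, threshold)
    )
    out: list[MentionRecord] = []
    for msg in candidates:
        tokens = [t.strip(_PUNCT) for t in msg.text.split()]
        tokens = [t for t in tokens if t]
        # hospital_id -> list of (start, end, distance, surface)
        matches: dict[str, list[tuple[int, int, int, str]]] = {}
        for start, end, span in _spans(tokens, max_ngram):
            # fuzzy matching only for spans no longer (in tokens) than the
            # longest alias; longer spans can still hit exactly
            exact_only = (end - start) > index.max_alias_tokens
            canonical, hid, dist = index.resolve(span, exact_only=exact_only)
            if canonical is None:
                continue
            matches.setdefault(hid, []).append((start, end, dist, span))  # type: ignore[arg-type]
        for hid, hits in sorted(matches.items()):
            if dedupe:
                start, end, dist, span = min(hits, key=lambda h: (h[2], h[0]))
                out.append(
                    MentionRecord(
                        message_id=msg.message_id,
                        hospital_id=hid,
                        surface_form=span,
                        distance=dist,
                        sentiment=msg.sentiment,
                    )
                )
            else:
                for start, end, dist, span in _merge_occurrences(hits):
                    out.append(
                        MentionRecord(
                            message_id=msg.message_id,
                            hospital_id=hid,
                            surface_form=span,
                            distance=dist,
                            sentiment=msg.sentiment,
                        )
                    )
    return out


def _merge_occurrences(
    hits: list[tuple[int, int, int, str]],
) -> list[tuple[int, int, int, str]]:
    """Collapse overlapping matched token intervals into one occurrence
    each, keeping the best (lowest-distance) span of every group."""
    merged: list[tuple[int, int, int, str]] = []
    for start, end, dist, span in sorted(hits):
        if merged and start < merged[-1][1]:
            pstart, pend, pdist, pspan = merged[-1]
            best = (dist, span) if dist < pdist else (pdist, pspan)
            merged[-1] = (pstart, max(pend, end), best[0], best[1])
        else:
            merged.append((start, end, dist, span))
    return merged


def filter_sentiment(
    mentions: Sequence[MentionRecord],
    unlabeled_policy: str = "keep",
) -> list[MentionRecord]:
    """Drop negative mentions; keep positive, neutral and ambiguous ones
    (ambiguous counts as neutral).  ``unlabeled_policy`` decides what to do
    with unlabeled sentiment: ``"keep"`` (default), ``"drop"``, or
    ``"error"``."""
    if unlabeled_policy not in ("keep", "drop", "error"):
        raise ValueError(f"unknown unlabeled_policy {unlabeled_policy!r}")
    out = []
    for m in mentions:
        if m.sentiment in RETAINED_SENTIMENTS:
            out.append(m)
        elif m.sentiment == "unlabeled":
            if unlabeled_policy == "error":
                raise ValueError(f"unlabeled sentiment on message {m.message_id}")
            if unlabeled_policy == "keep":
                out.append(m)
    return out


def evaluate_extraction(
    predicted: Sequence[MentionRecord],
    gold: GroundTruth | Mapping[str, set[str]],
    sample_fraction: float = 1.0,
    seed: int | np.random.Generator | None = None,
    message_ids: Sequence[str] | None = None,
) -> EvalMetrics:
    """Precision, recall and F1 of extraction against gold mention sets on
    a random message sample.

    The unit of evaluation is the (message, hospital) pair.  ``message_ids``
    defines the evaluation universe (defaulting to all messages appearing
    in predictions or gold); ``sample_fraction`` of it is sampled without
    replacement.
    """
    if not 0.0 < sample_fraction <= 1.0:
        raise ValueError("sample_fraction must be in (0, 1]")
    gold_map = gold.mentions if isinstance(gold, GroundTruth) else gold
    if message_ids is None:
        universe = sorted({m.message_id for m in predicted} | set(gold_map))
    else:
        universe = sorted(set(message_ids))
    if not universe:
        raise ValueError("empty evaluation sample")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    k = max(1, int(round(sample_fraction * len(universe))))
    sampled = set(rng.choice(universe, size=k, replace=False)) if k < len(universe) else set(universe)

    pred_pairs = {
        (m.message_id, m.hospital_id) for m in predicted if m.message_id in sampled
    }
    gold_pairs = {
        (mid, hid) for mid in sampled for hid in gold_map.get(mid, set())
    }
    tp = len(pred_pairs & gold_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else 0.0
    recall = tp / len(gold_pairs) if gold_pairs else (1.0 if not pred_pairs else 0.0)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return EvalMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        n_messages=len(sampled),
        n_predicted=len(pred_pairs),
        n_gold=len(gold_pairs),
    )
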