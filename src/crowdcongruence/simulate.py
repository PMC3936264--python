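"""Synthetic study generator with known ground truth.

Emulates the statistical structure the analysis assumes: a registry of
pediatric clinics per district with official antibiotic-prescription
rates; an alias dictionary whose surface forms are acronyms, truncations
and misspellings of the canonical names; district covariates drawn around
published census moments; and per-district message streams in which the
frequency of positive/neutral clinic mentions is a monotone function of
*perceived* quality — true quality (the negated prescription rate) plus
Gaussian noise whose standard deviation is a linear function of the
district's covariates.  The covariate-to-noise link gives the downstream
congruence regression known recoverable signs.

Two design choices matter for the exact noiseless limit.  First,
per-clinic retained-mention counts are allocated deterministically
(largest-remainder rounding of the softmax expectation over perceived
quality, followed by a strict-monotone repair along the perceived order)
rather than sampled per reply, so with zero noise and zero corruption the
crowd ranking reproduces the government ranking exactly.  Second,
negative-sentiment replies carry *background* mentions of uniformly random
clinics, so the downstream sentiment filter removes exactly the background
and leaves the allocated signal counts intact.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy.random.SeedSequence`` children (registry, aliases, demographics,
corpus, study — in that order), so each sub-stream is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import datasets
from .congruence import kendall_tau, spearman_rho
from .corpus import AliasDictionary, GroundTruth, Hospital, Message, Thread
from .demographics import DistrictDemographics
from .distance import levenshtein
from .extract import default_threshold

__all__ = [
    "SimulationConfig",
    "SimulationOutput",
    "FILLER_VOCAB",
    "make_registry",
    "make_aliases",
    "simulate_demographics",
    "simulate_education_counts",
    "simulate_corpus",
    "simulate_district_study",
    "generate_study",
    "render_html",
]

#: Filler vocabulary for message text.  Words are at most four characters
#: long, so multi-word filler spans stay far (in edit distance) from the
#: long clinic-name aliases; alias generation additionally rejects any
#: variant within matching distance of these words.
FILLER_VOCAB = (
    "the and my kid was so we go to a is it for our son she he had very "
    "nice good kind wait long time near home went last week fast care cold "
    "baby not with they them area best open late busy door meds shot fee "
    "pay told see ask new"
).split()

#: Words that may appear in messages outside the filler vocabulary.
_RESERVED_WORDS = set(FILLER_VOCAB) | {
    "pediatric",
    "recommendation",
    "please",
    "share",
    "clinic",
}

_CONSONANTS = "bdfgjklmnprstvz"
_VOWELS = "aeiou"
_NAME_ALPHABET = _CONSONANTS + _VOWELS

#: Default link between z-scored district covariates and the SD of the
#: perceived-quality noise.  Positive coefficients on birthrate, education
#: SD, density and doctors-per-clinic make congruence fall with those
#: covariates, the direction the regression should recover.  The scale
#: (noise SD a few times the clinic-quality spread of ~0.16) is calibrated
#: so that per-district tau values span the weak-congruence range the real
#: study observed (roughly -0.5 to +1 with most mass well below 1) and the
#: covariate regression explains about a third of the variance.
DEFAULT_NOISE_COEFFICIENTS: dict[str, float] = {
    "intercept": 0.45,
    "birthrate": 0.20,
    "education_mean": 0.0,
    "education_sd": 0.10,
    "population_density": 0.10,
    "doctors_per_clinic": 0.10,
    "availability": 0.0,
}

#: Education-category probabilities (categories as in
#: ``demographics.EDUCATION_YEARS`` order) whose weighted mean/SD of years
#: of schooling sit near the published census moments (12.39, 3.50).
DEFAULT_EDUCATION_PROBS = (0.015, 0.065, 0.14, 0.43, 0.115, 0.18, 0.04, 0.015)


def _covariate_params_default() -> dict[str, tuple[float, float]]:
    return {
        name: (float(row["mean"]), float(row["sd"]))
        for name, row in datasets.COVARIATE_SUMMARY.iterrows()
    }


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults reproduce the published study conditions where those are
    known: 29 districts, 779 clinics when per-district counts are supplied,
    5.36 messages per thread, a 92.03/7.97 positive-or-neutral/negative
    sentiment split, three alias surface forms per clinic on average, and
    census covariate moments as generative means/SDs.
    """

    n_districts: int = 29
    hospitals_per_district: int | Sequence[int] = 27
    beta_params: tuple[float, float] = (2.0, 5.0)
    threads_per_district: int = 60
    messages_per_thread_mean: float = 5.36
    qualifying_fraction: float = 0.8
    mention_rate: float = 1.0
    mean_aliases: float = 3.0
    typo_dmax: int = 1
    sentiment_mix: tuple[float, float, float, float] = (0.6203, 0.30, 0.0797, 0.0)
    corruption_rate: float = 0.1
    softmax_temperature: float = 0.15
    noise_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_COEFFICIENTS)
    )
    covariate_params: dict[str, tuple[float, float]] = field(
        default_factory=_covariate_params_default
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_districts < 1:
            raise ValueError("n_districts must be positive")
        counts = self.district_hospital_counts()
        if any(c < 1 for c in counts):
            raise ValueError("hospitals_per_district entries must be positive")
        if self.threads_per_district < 1:
            raise ValueError("threads_per_district must be positive")
        if self.messages_per_thread_mean < 1.0:
            raise ValueError("messages_per_thread_mean must be >= 1 (the root)")
        if not 0.0 <= self.qualifying_fraction <= 1.0:
            raise ValueError("qualifying_fraction must be in [0,1]")
        if self.mention_rate < 0:
            raise ValueError("mention_rate must be non-negative")
        mix = self.sentiment_mix
        if len(mix) != 4 or any(not 0.0 <= p <= 1.0 for p in mix):
            raise ValueError("sentiment_mix needs 4 probabilities in [0,1]")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("sentiment_mix must sum to 1")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must be in [0,1]")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be positive")
        if self.typo_dmax < 0:
            raise ValueError("typo_dmax must be non-negative")

    def district_hospital_counts(self) -> list[int]:
        if isinstance(self.hospitals_per_district, int):
            return [self.hospitals_per_district] * self.n_districts
        counts = list(self.hospitals_per_district)
        if len(counts) != self.n_districts:
            raise ValueError(
                f"hospitals_per_district has {len(counts)} entries for "
                f"{self.n_districts} districts"
            )
        return [int(c) for c in counts]

    def district_ids(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_districts)]

    def spawn_rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ("registry", "aliases", "demographics", "corpus", "study")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SimulationOutput:
    registry: list[Hospital]
    aliases: AliasDictionary
    demographics: list[DistrictDemographics]
    threads: list[Thread]
    messages: list[Message]
    gold: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# registry and aliases


def _name_token(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))]
        + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


def make_registry(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[Hospital]:
    """Clinics per district with Beta-distributed antibiotic rates.

    Canonical names are three whitespace-delimited tokens
    (``"<name> <name> clinic"``) with globally unique name parts, so that
    downstream token n-gram extraction sees realistic multi-token names.
    """
    rng = rng if rng is not None else config.spawn_rngs()["registry"]
    a, b = config.beta_params
    separator = _NameSeparator()
    registry: list[Hospital] = []
    for district_id, n_hosp in zip(config.district_ids(), config.district_hospital_counts()):
        for j in range(n_hosp):
            while True:
                t1 = _name_token(rng, int(rng.integers(3, 5)))
                t2 = _name_token(rng, int(rng.integers(3, 5)))
                canonical = f"{t1} {t2} clinic"
                if t1 not in _RESERVED_WORDS and separator.accept(canonical):
                    break
            rate = float(np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6))
            registry.append(
                Hospital(
                    hospital_id=f"{district_id}-H{j + 1:03d}",
                    canonical_name=canonical,
                    district_id=district_id,
                    antibiotic_rate=rate,
                    n_doctors=1 + int(rng.poisson(0.641)),
                )
            )
    return registry


class _NameSeparator:
    """Keeps accepted canonical names mutually distant in edit distance.

    Distinct clinics' full names must stay farther apart than the fuzzy
    matching threshold of the longest name (len//4, at most 6 here), or an
    exactly written name could resolve to a second clinic.  Candidates are
    pruned with character-count vectors before the dynamic program runs.
    """

    #: strictly greater than any default_threshold() of a canonical name
    MIN_DISTANCE = 7

    def __init__(self) -> None:
        self._names: list[str] = []
        self._vecs: list[np.ndarray] = []
        self._lens: list[int] = []

    @staticmethod
    def _vec(name: str) -> np.ndarray:
        v = np.zeros(27, dtype=np.int16)
        for ch in name:
            v[ord(ch) - 97 if "a" <= ch <= "z" else 26] += 1
        return v

    def accept(self, name: str) -> bool:
        v = self._vec(name)
        limit = self.MIN_DISTANCE - 1
        if self._names:
            mat = np.stack(self._vecs)
            l1 = np.abs(mat - v).sum(axis=1)
            close = np.nonzero(
                ((l1 + 1) // 2 <= limit)
                & (np.abs(np.array(self._lens) - len(name)) <= limit)
            )[0]
            for idx in close:
                if levenshtein(name, self._names[int(idx)], limit=limit) <= limit:
                    return False
        self._names.append(name)
        self._vecs.append(v)
        self._lens.append(len(name))
        return True


def _random_edits(word: str, n_edits: int, rng: np.random.Generator) -> str:
    chars = list(word)
    for _ in range(n_edits):
        op = rng.integers(3)
        pos = int(rng.integers(len(chars))) if chars else 0
        ch = _NAME_ALPHABET[rng.integers(len(_NAME_ALPHABET))]
        if op == 0 and len(chars) > 2:  # deletion
            del chars[pos]
        elif op == 1:  # insertion
            chars.insert(pos, ch)
        else:  # substitution
            if chars:
                chars[pos] = ch
    return "".join(chars)


def _alias_is_safe(alias: str, used: set[str]) -> bool:
    """A new surface form must be globally unique and, if short enough to
    be fuzzily reachable from everyday words, must not lie within its
    matching threshold of any reserved word."""
    if not alias or alias in used or alias in _RESERVED_WORDS:
        return False
    if len(alias) <= 7:
        thr = default_threshold(alias)
        for w in _RESERVED_WORDS:
            if levenshtein(alias, w, limit=thr) <= thr:
                return False
    return True


def make_aliases(
    registry: Sequence[Hospital],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> AliasDictionary:
    """Alias dictionary with acronyms (initial-character contraction),
    truncations (the leading name token) and typo variants within
    ``typo_dmax`` edits of their source; the canonical name itself is
    always a member.  With ``mean_aliases=0`` only the identity remains.
    """
    if not registry:
        raise ValueError("registry is empty")
    rng = rng if rng is not None else config.spawn_rngs()["aliases"]
    entries: dict[str, set[str]] = {}
    hospital_ids: dict[str, str] = {}
    used: set[str] = {h.canonical_name for h in registry}
    typo_mean = max(0.0, config.mean_aliases - 2.0)
    for h in registry:
        forms: set[str] = {h.canonical_name}
        hospital_ids[h.canonical_name] = h.hospital_id
        if config.mean_aliases > 0:
            tokens = h.canonical_name.split()
            acronym = "".join(t[0] for t in tokens)
            if _alias_is_safe(acronym, used):
                forms.add(acronym)
                used.add(acronym)
            truncation = tokens[0]
            if _alias_is_safe(truncation, used):
                forms.add(truncation)
                used.add(truncation)
            n_typos = int(rng.poisson(typo_mean)) if typo_mean > 0 else 0
            for _ in range(n_typos):
                for _attempt in range(10):
                    n_edits = 1 + int(rng.integers(config.typo_dmax)) if config.typo_dmax > 1 else min(1, config.typo_dmax)
                    if n_edits == 0:
                        break
                    variant = _random_edits(tokens[0], n_edits, rng)
                    if _alias_is_safe(variant, used):
                        forms.add(variant)
                        used.add(variant)
                        break
        entries[h.canonical_name] = forms
    _prune_confusable_variants(entries, hospital_ids)
    return AliasDictionary(entries=entries, hospital_ids=hospital_ids)


def _prune_confusable_variants(
    entries: dict[str, set[str]], hospital_ids: dict[str, str]
) -> None:
    """Drop fuzzy-matchable variants that another clinic's rendered text
    could reach within their edit-distance threshold.

    When a clinic's canonical name is written out, each of its tokens (and
    every other alias) appears as a span; if such a span lies within the
    matching threshold of a *different* clinic's variant, uncorrupted
    messages would produce cross-clinic false positives.  Those variants
    are removed; canonical names and exact-only acronyms stay.
    """
    # protected spans a clinic's own messages can contain
    protected: list[tuple[str, str]] = []  # (span, hospital_id)
    for canonical, forms in entries.items():
        hid = hospital_ids.get(canonical, canonical)
        for tok in canonical.split():
            protected.append((tok, hid))
        for alias in forms:
            if " " not in alias:
                protected.append((alias, hid))

    # fuzzy-matchable single-token variants (threshold >= 1)
    variants: list[tuple[str, int, str, str]] = []  # (alias, thr, canonical, hid)
    for canonical, forms in entries.items():
        hid = hospital_ids.get(canonical, canonical)
        for alias in forms:
            if alias == canonical or " " in alias:
                continue
            thr = default_threshold(alias)
            if thr >= 1:
                variants.append((alias, thr, canonical, hid))
    if not variants:
        return

    alphabet = sorted({ch for a, _, _, _ in variants for ch in a})
    col = {ch: i for i, ch in enumerate(alphabet)}
    mat = np.zeros((len(variants), len(alphabet) + 1), dtype=np.int16)
    for row, (alias, _, _, _) in enumerate(variants):
        for ch in alias:
            mat[row, col[ch]] += 1
    lens = np.array([len(a) for a, _, _, _ in variants], dtype=np.int16)
    thrs = np.array([t for _, t, _, _ in variants], dtype=np.int16)

    doomed: set[tuple[str, str]] = set()
    other = len(alphabet)
    for span, span_hid in protected:
        vec = np.zeros(len(alphabet) + 1, dtype=np.int16)
        for ch in span:
            vec[col.get(ch, other)] += 1
        l1 = np.abs(mat - vec).sum(axis=1)
        close = np.nonzero(
            (np.abs(lens - len(span)) <= thrs) & ((l1 + 1) // 2 <= thrs)
        )[0]
        for idx in close:
            alias, thr, canonical, hid = variants[int(idx)]
            if hid == span_hid or (canonical, alias) in doomed:
                continue
            if levenshtein(span, alias, limit=thr) <= thr:
                doomed.add((canonical, alias))
    for canonical, alias in doomed:
        entries[canonical].discard(alias)


# ---------------------------------------------------------------------------
# demographics


def simulate_demographics(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[DistrictDemographics]:
    """District covariates drawn around the configured generative moments.

    The six covariates are drawn as independent (clipped) normals; raw
    census quantities (population, area, clinic and doctor head counts)
    are then derived so that the record's internal identities — density =
    population/(area_km2*1e6), availability = 1000*clinics/population —
    hold exactly after integer rounding of head counts.
    """
    rng = rng if rng is not None else config.spawn_rngs()["demographics"]
    p = config.covariate_params
    out: list[DistrictDemographics] = []
    for district_id in config.district_ids():
        birthrate = float(max(0.2, rng.normal(*p["birthrate"])))
        edu_mean = float(np.clip(rng.normal(*p["education_mean"]), 6.0, 20.0))
        edu_sd = float(max(0.3, rng.normal(*p["education_sd"])))
        density = float(max(0.001, rng.normal(*p["population_density"])))
        dpc = float(max(1.0, rng.normal(*p["doctors_per_clinic"])))
        avail = float(max(0.005, rng.normal(*p["availability"])))
        population = float(max(50_000.0, rng.normal(430_000.0, 120_000.0)))
        area_km2 = population / (density * 1e6)
        n_clinics = max(1, int(round(avail * population / 1000.0)))
        n_doctors = max(n_clinics, int(round(dpc * n_clinics)))
        out.append(
            DistrictDemographics(
                district_id=district_id,
                birthrate=birthrate,
                education_mean=edu_mean,
                education_sd=edu_sd,
                population=population,
                area_km2=area_km2,
                population_density=density,
                doctors_per_clinic=n_doctors / n_clinics,
                availability=1000.0 * n_clinics / population,
            )
        )
    return out


def simulate_education_counts(
    n_women: int,
    rng: np.random.Generator,
    probs: Sequence[float] = DEFAULT_EDUCATION_PROBS,
) -> np.ndarray:
    """Multinomial census counts over the eight education categories."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (8,) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be 8 probabilities summing to 1")
    return rng.multinomial(n_women, probs)


def _noise_sd(config: SimulationConfig, demo: DistrictDemographics) -> float:
    coeffs = config.noise_coefficients
    sd = coeffs.get("intercept", 0.0)
    for name, (mean, scale) in config.covariate_params.items():
        c = coeffs.get(name, 0.0)
        if c != 0.0:
            z = (getattr(demo, name) - mean) / scale
            sd += c * z
    return max(0.0, sd)


# ---------------------------------------------------------------------------
# mention-count allocation


def _softmax(values: np.ndarray, temperature: float) -> np.ndarray:
    z = (values - values.max()) / temperature
    w = np.exp(z)
    return w / w.sum()


def _allocate_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Deterministic integer allocation of ``total`` mentions over clinics
    ordered by descending perceived quality.

    Counts must be strictly decreasing over the mentioned prefix so the
    induced frequency ranking is tie-free and equals the perceived-quality
    ranking.  A strictly decreasing positive sequence over k clinics needs
    at least k(k+1)/2 mentions, so only the top k = O(sqrt(total)) clinics
    receive mentions: a unit staircase (k, k-1, ..., 1) guarantees
    strictness, and the remaining budget is spread over the top k by
    largest-remainder rounding of the renormalized softmax weights, sorted
    decreasing.  The total is preserved exactly.
    """
    n = len(weights)
    counts = np.zeros(n, dtype=int)
    if total <= 0 or n == 0:
        return counts
    # largest k with k(k+1)/2 <= total
    k = min(n, int((math.isqrt(8 * total + 1) - 1) // 2))
    if k == 0:
        return counts
    stair = np.arange(k, 0, -1)
    extra_total = total - k * (k + 1) // 2
    w = weights[:k] / weights[:k].sum()
    target = extra_total * w
    extra = np.floor(target).astype(int)
    short = extra_total - extra.sum()
    if short > 0:
        remainders = target - extra
        # ties broken toward better-ranked clinics (stable argsort on -rem)
        for idx in np.argsort(-remainders, kind="stable")[:short]:
            extra[idx] += 1
    counts[:k] = stair + np.sort(extra)[::-1]
    return counts


# ---------------------------------------------------------------------------
# corpus


_SENTIMENT_LABELS = ("positive", "neutral", "negative", "ambiguous")


def simulate_corpus(
    registry: Sequence[Hospital],
    aliases: AliasDictionary,
    demographics: Sequence[DistrictDemographics],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Thread], list[Message], GroundTruth]:
    """Per-district threads and messages with gold mention annotations.

    Qualifying threads open with a pediatric-recommendation request; their
    positive/neutral replies carry the allocated signal mentions (at most
    one mention of a given clinic per message, so message-level
    deduplication is lossless) and their negative replies carry background
    mentions of uniformly random clinics.  Mentions are rendered through a
    sampled alias and further corrupted with probability
    ``corruption_rate``.
    """
    rng = rng if rng is not None else config.spawn_rngs()["corpus"]
    demo_by_district = {d.district_id: d for d in demographics}
    district_ids = sorted({h.district_id for h in registry})
    missing = [d for d in district_ids if d not in demo_by_district]
    if missing:
        raise ValueError(f"no demographics for districts {missing}")

    threads: list[Thread] = []
    messages: list[Message] = []
    gold_mentions: dict[str, set[str]] = {}
    perceived_ranking: dict[str, list[str]] = {}
    noise_sd: dict[str, float] = {}

    mix = np.asarray(config.sentiment_mix, dtype=float)

    for district_id in district_ids:
        hospitals = sorted(
            (h for h in registry if h.district_id == district_id),
            key=lambda h: h.hospital_id,
        )
        sigma = _noise_sd(config, demo_by_district[district_id])
        noise_sd[district_id] = sigma
        quality = np.array([-h.antibiotic_rate for h in hospitals])
        perceived = quality + (rng.normal(0.0, sigma, len(hospitals)) if sigma > 0 else 0.0)
        order = sorted(range(len(hospitals)), key=lambda i: (-perceived[i], hospitals[i].hospital_id))
        perceived_ranking[district_id] = [hospitals[i].hospital_id for i in order]

        # skeleton: threads with roots and replies
        reply_meta: list[dict] = []  # one dict per reply, mutated below
        for t in range(config.threads_per_district):
            thread_id = f"{district_id}-T{t + 1:04d}"
            threads.append(Thread(thread_id=thread_id, district_id=district_id))
            qualifying = bool(rng.random() < config.qualifying_fraction)
            n_replies = int(rng.poisson(config.messages_per_thread_mean - 1.0))
            root_words = list(rng.choice(FILLER_VOCAB, size=5))
            if qualifying:
                root_text = "pediatric recommendation please " + " ".join(root_words)
            else:
                root_text = " ".join(root_words)
            messages.append(
                Message(
                    message_id=f"{thread_id}-M000",
                    thread_id=thread_id,
                    district_id=district_id,
                    is_reply=False,
                    text=root_text,
                    sentiment="unlabeled",
                )
            )
            for r in range(n_replies):
                sentiment = _SENTIMENT_LABELS[int(rng.choice(4, p=mix))]
                reply_meta.append(
                    {
                        "message_id": f"{thread_id}-M{r + 1:03d}",
                        "thread_id": thread_id,
                        "qualifying": qualifying,
                        "sentiment": sentiment,
                        "mentions": [],
                    }
                )

        retained = [
            m
            for m in reply_meta
            if m["qualifying"] and m["sentiment"] in ("positive", "neutral", "ambiguous")
        ]
        negatives = [m for m in reply_meta if m["qualifying"] and m["sentiment"] == "negative"]

        total_mentions = int(round(config.mention_rate * len(retained)))
        weights = _softmax(perceived[order], config.softmax_temperature)
        counts = _allocate_counts(weights, total_mentions)
        for rank_pos, c in enumerate(counts):
            if c <= 0:
                continue
            hospital = hospitals[order[rank_pos]]
            c = min(int(c), len(retained))
            chosen = rng.choice(len(retained), size=c, replace=False)
            for idx in chosen:
                retained[int(idx)]["mentions"].append(hospital)
        for m in negatives:
            m["mentions"].append(hospitals[int(rng.integers(len(hospitals)))])

        # render reply text; surfaces are inserted as atomic chunks so a
        # later insertion can never split an earlier mention's tokens
        for m in reply_meta:
            n_filler = int(rng.integers(4, 10))
            chunks = list(rng.choice(FILLER_VOCAB, size=n_filler))
            mentioned: set[str] = set()
            for hospital in m["mentions"]:
                surface = _render_surface(hospital, aliases, config, rng)
                pos = int(rng.integers(len(chunks) + 1))
                chunks.insert(pos, surface)
                mentioned.add(hospital.hospital_id)
            messages.append(
                Message(
                    message_id=m["message_id"],
                    thread_id=m["thread_id"],
                    district_id=district_id,
                    is_reply=True,
                    text=" ".join(chunks),
                    sentiment=m["sentiment"],
                )
            )
            if mentioned:
                gold_mentions[m["message_id"]] = mentioned

    gold = GroundTruth(
        mentions=gold_mentions,
        perceived_ranking=perceived_ranking,
        noise_sd=noise_sd,
    )
    return threads, messages, gold


def _render_surface(
    hospital: Hospital,
    aliases: AliasDictionary,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    forms = sorted(aliases.entries[hospital.canonical_name])
    surface = forms[int(rng.integers(len(forms)))]
    if config.corruption_rate > 0 and rng.random() < config.corruption_rate:
        n_edits = min(4, int(rng.geometric(0.5)))
        surface = " ".join(
            _random_edits(tok, n_edits, rng) if i == 0 else tok
            for i, tok in enumerate(surface.split())
        )
    return surface


def generate_study(config: SimulationConfig) -> SimulationOutput:
    """Full synthetic study: registry, aliases, demographics, corpus and
    ground truth, all derived from ``config.seed``."""
    rngs = config.spawn_rngs()
    registry = make_registry(config, rngs["registry"])
    aliases = make_aliases(registry, config, rngs["aliases"])
    demographics = simulate_demographics(config, rngs["demographics"])
    threads, messages, gold = simulate_corpus(
        registry, aliases, demographics, config, rngs["corpus"]
    )
    return SimulationOutput(
        registry=registry,
        aliases=aliases,
        demographics=demographics,
        threads=threads,
        messages=messages,
        gold=gold,
        config=config,
    )


# ---------------------------------------------------------------------------
# district-level fast path


def simulate_district_study(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """District-level Monte-Carlo shortcut: covariates, noise SD and the
    resulting tau/rho per district, without rendering any text.

    Reproduces the generative chain perceived quality -> deterministic
    mention-count allocation -> aligned crowd/government rankings -> rank
    correlations, using the same allocation rule as the corpus generator.
    Intended for design checks and power studies of the congruence
    regression, where text extraction (verified separately to be lossless
    at zero corruption) would only add cost.
    """
    from scipy.stats import rankdata

    rng = rng if rng is not None else config.spawn_rngs()["study"]
    demographics = simulate_demographics(config, rng)
    a, b = config.beta_params
    p_retained = config.sentiment_mix[0] + config.sentiment_mix[1] + config.sentiment_mix[3]
    mean_replies = (
        config.threads_per_district
        * config.qualifying_fraction
        * (config.messages_per_thread_mean - 1.0)
        * p_retained
    )
    rows = []
    counts_per_district = config.district_hospital_counts()
    for demo, n_hosp in zip(demographics, counts_per_district):
        rates = np.clip(rng.beta(a, b, n_hosp), 1e-6, 1 - 1e-6)
        sigma = _noise_sd(config, demo)
        perceived = -rates + (rng.normal(0.0, sigma, n_hosp) if sigma > 0 else 0.0)
        order = np.argsort(-perceived, kind="stable")
        total = int(round(config.mention_rate * mean_replies))
        counts = _allocate_counts(_softmax(perceived[order], config.softmax_temperature), total)
        full_counts = np.zeros(n_hosp, dtype=int)
        full_counts[order] = counts
        mentioned = full_counts > 0
        n = int(mentioned.sum())
        if n >= 2:
            crowd = rankdata(-full_counts[mentioned], method="average")
            gov = rankdata(rates[mentioned], method="average")
            tau = kendall_tau(crowd, gov)
            rho = spearman_rho(crowd, gov)
        else:
            tau = rho = math.nan
        rows.append(
            {
                "district_id": demo.district_id,
                "birthrate": demo.birthrate,
                "education_mean": demo.education_mean,
                "education_sd": demo.education_sd,
                "population_density": demo.population_density,
                "doctors_per_clinic": demo.doctors_per_clinic,
                "availability": demo.availability,
                "noise_sd": sigma,
                "n": n,
                "kendall_tau": tau,
                "spearman_rho": rho,
            }
        )
    return pd.DataFrame(rows).set_index("district_id")


# ---------------------------------------------------------------------------
# HTML fixture writer


def render_html(messages: Sequence[Message], title: str = "community fixture") -> str:
    """Wrap messages in minimal forum-like markup (with a script block and
    an image tag) for exercising markup stripping."""
    parts = [
        "<html><head>",
        f"<title>{title}</title>",
        "<script>var tracker = 'not text';</script>",
        "<style>.msg { color: black; }</style>",
        "</head><body>",
        '<img src="banner.png" alt="">',
    ]
    for m in messages:
        parts.append(
            f'<div class="msg" id="{m.message_id}"><p>{m.text}</p></div>'
        )
    parts.append("</body></html>")
    return "\n".join(parts)


def noiseless(config: SimulationConfig) -> SimulationConfig:
    """Copy of ``config`` with zero perceived-quality noise and zero
    surface corruption — the exact-congruence limit."""
    coeffs = {k: 0.0 for k in config.noise_coefficients}
    return replace(config, noise_coefficients=coeffs, corruption_rate=0.0)
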