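"""Markup stripping, candidate filtering, stepwise normalization,
mention extraction, sentiment filtering and evaluation."""

import edlib
import pytest

from crowdcongruence.corpus import AliasDictionary, Message, Thread
from crowdcongruence.distance import levenshtein
from crowdcongruence.extract import (
    AliasIndex,
    default_threshold,
    evaluate_extraction,
    extract_mentions,
    filter_candidates,
    filter_sentiment,
    normalize_expression,
    strip_markup,
)
from crowdcongruence.simulate import render_html


# ---------------------------------------------------------------------------
# strip_markup


def test_strip_single_tag():
    assert strip_markup("<p>recommend A clinic</p>") == "recommend A clinic"


def test_plain_text_passes_through():
    text = "no markup here, just words"
    assert strip_markup(text) == text


def test_script_style_and_attributes_removed():
    html = (
        "<html><body><script>var x = 'secret';</script>"
        '<style>p { color: red; }</style>'
        '<p>go to <b>harbor bay clinic</b> now</p>'
        '<img src="banner.png" alt=""/></body></html>'
    )
    assert strip_markup(html) == "go to harbor bay clinic now"


def test_rendered_fixture_round_trip():
    msgs = [
        Message("m1", "t1", "D1", True, "visit harbor bay clinic", "positive"),
        Message("m2", "t1", "D1", True, "maple was fine", "neutral"),
    ]
    out = strip_markup(render_html(msgs))
    for m in msgs:
        assert m.text in out
    for forbidden in ("tracker", "not text", "banner.png", "color"):
        assert forbidden not in out


# ---------------------------------------------------------------------------
# filter_candidates


def _thread(tid, root_text, n_replies, district="D1"):
    msgs = [Message(f"{tid}-m0", tid, district, False, root_text)]
    msgs += [
        Message(f"{tid}-m{i + 1}", tid, district, True, f"reply {i}")
        for i in range(n_replies)
    ]
    return Thread(tid, district), msgs


def test_qualifying_thread_yields_its_replies():
    thread, msgs = _thread("t1", "pediatric recommendation please", 3)
    assert len(filter_candidates([thread], msgs)) == 3


def test_thread_without_keywords_yields_nothing():
    thread, msgs = _thread("t1", "selling a stroller", 5)
    assert filter_candidates([thread], msgs) == []


def test_mixed_corpus_counts_match_enumeration():
    roots = [
        ("pediatric recommendation?", 2),
        ("anyone know a good pediatric recommendation", 4),
        ("pediatric question only", 3),  # no request keyword
        ("recommendation for a plumber", 1),  # no domain keyword
        ("Pediatric RECOMMENDATION caps", 5),  # case-insensitive
        ("nothing relevant", 2),
        ("pediatric recommendation thread", 0),
        ("pediatric recommendation again", 3),
        ("chitchat", 6),
        ("more chitchat", 1),
    ]
    threads, messages = [], []
    expected = 0
    for i, (root, n) in enumerate(roots):
        t, msgs = _thread(f"t{i}", root, n)
        threads.append(t)
        messages.extend(msgs)
        low = root.casefold()
        if "pediatric" in low and "recommendation" in low:
            expected += n
    got = filter_candidates(threads, messages)
    assert len(got) == expected
    assert all(m.is_reply for m in got)


# ---------------------------------------------------------------------------
# normalize_expression


def test_canonical_name_is_fixed_point(tiny_aliases):
    name, dist = normalize_expression("harbor bay clinic", tiny_aliases)
    assert (name, dist) == ("harbor bay clinic", 0)


def test_acronym_resolves_exactly(tiny_aliases):
    assert normalize_expression("hbc", tiny_aliases) == ("harbor bay clinic", 0)


def test_case_and_whitespace_insensitive(tiny_aliases):
    assert normalize_expression("  Harbor   BAY  Clinic ", tiny_aliases) == (
        "harbor bay clinic",
        0,
    )


def test_fuzzy_match_verified_by_brute_force(tiny_aliases):
    surface = "harbpr"  # one substitution from alias "harbor"
    name, dist = normalize_expression(surface, tiny_aliases)
    # brute-force nearest-alias search with an independent distance
    best = min(
        (
            (edlib.align(surface, alias, task="distance")["editDistance"], canonical)
            for canonical, forms in tiny_aliases.entries.items()
            for alias in forms
        ),
    )
    assert name == best[1]
    assert dist == best[0] == 1


def test_empty_surface_is_unresolved(tiny_aliases):
    assert normalize_expression("   ", tiny_aliases) == (None, None)


def test_beyond_threshold_is_unresolved(tiny_aliases):
    # "hbx" is 1 edit from acronym "hbc", but 3-char aliases require
    # an exact match under the quarter-length rule
    assert normalize_expression("hbx", tiny_aliases) == (None, None)


def test_default_threshold_quarter_length_rule():
    assert default_threshold("abc") == 0
    assert default_threshold("abcd") == 1
    assert default_threshold("abcdefg") == 1
    assert default_threshold("abcdefgh") == 2


def test_idempotent_on_all_canonicals(small_study):
    index = AliasIndex(small_study.aliases)
    for canonical in small_study.aliases.entries:
        assert index.normalize(canonical) == (canonical, 0)


def test_tie_break_prefers_longer_alias_then_lexicographic():
    d = AliasDictionary(
        entries={
            "aaa bbb clinic": {"abcd"},
            "aaa ccc clinic": {"abce"},
        }
    )
    # distance 1 to both 4-char aliases: lexicographically smaller canonical
    assert normalize_expression("abcf", d) == ("aaa bbb clinic", 1)

    d2 = AliasDictionary(
        entries={
            "zzz yyy clinic": {"abcde"},  # longer alias, later canonical
            "aaa bbb clinic": {"abcd"},
        }
    )
    # distance 1 to both: the longer (more specific) alias wins
    assert normalize_expression("abcdx", d2) == ("zzz yyy clinic", 1)


def test_resolution_count_monotone_in_threshold(small_study):
    """Raising the distance threshold never unresolves a span."""
    replies = [m for m in small_study.messages if m.is_reply][:400]
    spans = sorted({tok for m in replies for tok in m.text.split()})
    resolved_sets = []
    for thr in (0, 1, 2, 3):
        index = AliasIndex(small_study.aliases, threshold=thr)
        resolved_sets.append({s for s in spans if index.normalize(s)[0] is not None})
    for lo, hi in zip(resolved_sets, resolved_sets[1:]):
        assert lo <= hi


# ---------------------------------------------------------------------------
# extract_mentions


def test_two_distinct_hits_two_records(tiny_aliases):
    msg = Message("m1", "t1", "D1", True, "we like hbc and also maple", "positive")
    records = extract_mentions([msg], tiny_aliases)
    assert {r.hospital_id for r in records} == {"D1-H1", "D1-H2"}


def test_duplicate_mention_deduplicated_per_message(tiny_aliases):
    msg = Message("m1", "t1", "D1", True, "hbc was great, go hbc", "positive")
    assert len(extract_mentions([msg], tiny_aliases)) == 1
    # occurrence-level counting is available by flag
    assert len(extract_mentions([msg], tiny_aliases, dedupe=False)) == 2


def test_overlapping_spans_are_one_occurrence(tiny_aliases):
    # "harbor bay clinic" matches as the full name and via nested spans;
    # occurrence-level counting must not multiply-count the same tokens
    msg = Message("m1", "t1", "D1", True, "went to harbor bay clinic today", "neutral")
    assert len(extract_mentions([msg], tiny_aliases, dedupe=False)) == 1


def test_recorded_distance_is_true_minimum(small_study):
    """Every record's distance equals the exact minimum edit distance from
    its surface to the matched clinic's alias set (independent aligner)."""
    replies = [m for m in small_study.messages if m.is_reply][:300]
    records = extract_mentions(replies, small_study.aliases)
    canonical_of = {h.hospital_id: h.canonical_name for h in small_study.registry}
    assert records, "fixture produced no mentions"
    for r in records:
        forms = small_study.aliases.entries[canonical_of[r.hospital_id]]
        surface = " ".join(r.surface_form.split()).casefold()
        true_min = min(
            edlib.align(surface, alias, task="distance")["editDistance"]
            if surface != alias
            else 0
            for alias in forms
        )
        assert r.distance == true_min


def test_mention_sentiment_inherited(tiny_aliases):
    msg = Message("m1", "t1", "D1", True, "hbc", "negative")
    (rec,) = extract_mentions([msg], tiny_aliases)
    assert rec.sentiment == "negative"


# ---------------------------------------------------------------------------
# filter_sentiment


def _mentions_with(sentiments):
    from crowdcongruence.corpus import MentionRecord

    return [
        MentionRecord(f"m{i}", "D1-H1", "hbc", 0, s) for i, s in enumerate(sentiments)
    ]


def test_negative_mentions_dropped():
    mentions = _mentions_with(["positive"] * 80 + ["neutral"] * 12 + ["negative"] * 8)
    assert len(filter_sentiment(mentions)) == 92


def test_all_positive_unchanged():
    mentions = _mentions_with(["positive"] * 10)
    assert filter_sentiment(mentions) == mentions


def test_ambiguous_treated_as_neutral():
    mentions = _mentions_with(["ambiguous", "negative"])
    kept = filter_sentiment(mentions)
    assert [m.sentiment for m in kept] == ["ambiguous"]


def test_unlabeled_policy():
    mentions = _mentions_with(["unlabeled", "positive"])
    assert len(filter_sentiment(mentions, unlabeled_policy="keep")) == 2
    assert len(filter_sentiment(mentions, unlabeled_policy="drop")) == 1
    with pytest.raises(ValueError):
        filter_sentiment(mentions, unlabeled_policy="error")


# ---------------------------------------------------------------------------
# evaluate_extraction


def test_perfect_extraction_scores_one():
    gold = {"m1": {"h1"}, "m2": {"h2", "h3"}}
    predicted = _pairs_to_records([("m1", "h1"), ("m2", "h2"), ("m2", "h3")])
    m = evaluate_extraction(predicted, gold)
    assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)


def test_f1_harmonic_mean_of_printed_precision_recall():
    """P = 0.84 and R = 0.73 give F1 = 2PR/(P+R) = 0.7811..., i.e. 78.1%
    to one decimal (the harmonic-mean formula, evaluated exactly)."""
    # TP/gold = 73/100 and TP/pred = 21/25 jointly need TP = 1533,
    # gold = 2100, predicted = 1825
    gold_pairs = [(f"m{i}", "h") for i in range(2100)]
    pred_pairs = gold_pairs[:1533] + [(f"m{i}", "x") for i in range(292)]
    gold = {}
    for mid, hid in gold_pairs:
        gold.setdefault(mid, set()).add(hid)
    m = evaluate_extraction(_pairs_to_records(pred_pairs), gold)
    assert m.precision == pytest.approx(0.84, abs=1e-12)
    assert m.recall == pytest.approx(0.73, abs=1e-12)
    assert m.f1 == pytest.approx(2 * 0.84 * 0.73 / (0.84 + 0.73), abs=1e-12)
    assert round(100 * m.f1, 1) == 78.1


def test_no_predictions_convention():
    m = evaluate_extraction([], {"m1": {"h1"}})
    assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)


def test_empty_sample_is_error():
    with pytest.raises(ValueError):
        evaluate_extraction([], {})
    with pytest.raises(ValueError):
        evaluate_extraction([], {"m1": {"h1"}}, sample_fraction=0.0)


def test_sampling_is_seeded_and_partial():
    gold = {f"m{i}": {"h1"} for i in range(100)}
    predicted = _pairs_to_records([(f"m{i}", "h1") for i in range(50)])
    a = evaluate_extraction(predicted, gold, sample_fraction=0.2, seed=4)
    b = evaluate_extraction(predicted, gold, sample_fraction=0.2, seed=4)
    assert a == b
    assert a.n_messages == 20


def _pairs_to_records(pairs):
    from crowdcongruence.corpus import MentionRecord

    return [MentionRecord(mid, hid, hid, 0, "positive") for mid, hid in pairs]
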