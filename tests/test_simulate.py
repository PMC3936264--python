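"""Synthetic-study generator: determinism, registry shape, alias
construction, demographic moments, corpus statistics and the
covariate-to-noise design."""

import edlib
import numpy as np
import pytest

from crowdcongruence import datasets
from crowdcongruence.simulate import (
    FILLER_VOCAB,
    SimulationConfig,
    _allocate_counts,
    generate_study,
    make_aliases,
    make_registry,
    noiseless,
    simulate_demographics,
    simulate_district_study,
    simulate_education_counts,
)
from crowdcongruence.demographics import education_stats


def test_seed_reproducibility_is_exact():
    config = SimulationConfig(
        n_districts=3, hospitals_per_district=6, threads_per_district=10, seed=21
    )
    a = generate_study(config)
    b = generate_study(config)
    assert [h.__dict__ for h in a.registry] == [h.__dict__ for h in b.registry]
    assert a.aliases.entries == b.aliases.entries
    assert [m.__dict__ for m in a.messages] == [m.__dict__ for m in b.messages]
    assert a.gold.mentions == b.gold.mentions


def test_registry_published_district_counts_total_779():
    config = SimulationConfig(
        n_districts=len(datasets.DISTRICT_CLINIC_COUNTS),
        hospitals_per_district=datasets.DISTRICT_CLINIC_COUNTS,
        seed=0,
    )
    registry = make_registry(config)
    assert len(registry) == 779
    per_district = {}
    for h in registry:
        per_district[h.district_id] = per_district.get(h.district_id, 0) + 1
    assert sorted(per_district.values()) == sorted(datasets.DISTRICT_CLINIC_COUNTS)
    assert all(0 <= h.antibiotic_rate <= 1 for h in registry)
    assert all(h.n_doctors >= 1 for h in registry)


def test_single_hospital_districts():
    config = SimulationConfig(n_districts=4, hospitals_per_district=1, seed=1)
    registry = make_registry(config)
    assert len(registry) == 4
    assert len({h.district_id for h in registry}) == 4


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_districts=0)
    with pytest.raises(ValueError):
        SimulationConfig(hospitals_per_district=0)
    with pytest.raises(ValueError):
        SimulationConfig(sentiment_mix=(0.5, 0.5, 0.5, 0.0))
    with pytest.raises(ValueError):
        SimulationConfig(corruption_rate=1.5)


def test_alias_sets_contain_identity_and_average_near_three():
    config = SimulationConfig(n_districts=8, hospitals_per_district=25, seed=2)
    registry = make_registry(config)
    aliases = make_aliases(registry, config)
    for canonical, forms in aliases.entries.items():
        assert canonical in forms
    # about three similar expressions (non-identity forms) per clinic
    assert 2.0 <= aliases.mean_alias_count() <= 4.0


def test_corruption_disabled_gives_identity_sets():
    config = SimulationConfig(
        n_districts=2, hospitals_per_district=4, mean_aliases=0.0, seed=3
    )
    registry = make_registry(config)
    aliases = make_aliases(registry, config)
    for canonical, forms in aliases.entries.items():
        assert forms == {canonical}


def test_typo_variants_within_dmax_of_source():
    """Every generated variant is an acronym, a truncation, or within
    typo_dmax edits of the leading name token (checked with an
    independent aligner)."""
    config = SimulationConfig(n_districts=6, hospitals_per_district=20, typo_dmax=1, seed=4)
    registry = make_registry(config)
    aliases = make_aliases(registry, config)
    for h in registry:
        tokens = h.canonical_name.split()
        acronym = "".join(t[0] for t in tokens)
        for alias in aliases.entries[h.canonical_name]:
            if alias in (h.canonical_name, acronym, tokens[0]):
                continue
            d = edlib.align(alias, tokens[0], task="distance")["editDistance"]
            assert 1 <= d <= config.typo_dmax


def test_aliases_never_collide_with_filler_vocabulary():
    config = SimulationConfig(n_districts=6, hospitals_per_district=20, seed=5)
    registry = make_registry(config)
    aliases = make_aliases(registry, config)
    assert not (aliases.all_surfaces() & set(FILLER_VOCAB))


def test_demographic_sample_means_match_generative_moments():
    config = SimulationConfig(n_districts=1000, hospitals_per_district=1, seed=6)
    demos = simulate_demographics(config)
    birthrates = np.array([d.birthrate for d in demos])
    se = 0.100 / np.sqrt(len(demos))
    assert abs(birthrates.mean() - 1.048) < 3 * se
    # internal identities hold exactly
    for d in demos[:50]:
        assert d.population_density == pytest.approx(d.population / (d.area_km2 * 1e6))
        assert d.availability > 0 and d.doctors_per_clinic >= 1


def test_zero_variance_demographics_are_identical():
    params = {k: (m, 0.0) for k, (m, _) in SimulationConfig().covariate_params.items()}
    config = SimulationConfig(n_districts=5, covariate_params=params, seed=7)
    demos = simulate_demographics(config)
    first = demos[0]
    for d in demos[1:]:
        assert d.birthrate == first.birthrate
        assert d.education_mean == first.education_mean
        assert d.education_sd == first.education_sd


def test_messages_per_thread_mean():
    config = SimulationConfig(
        n_districts=1, hospitals_per_district=5, threads_per_district=2000, seed=8
    )
    study = generate_study(config)
    per_thread = {}
    for m in study.messages:
        per_thread[m.thread_id] = per_thread.get(m.thread_id, 0) + 1
    means = np.array(list(per_thread.values()), dtype=float)
    se = np.sqrt(4.36) / np.sqrt(len(means))
    assert abs(means.mean() - 5.36) < 3 * se


def test_sentiment_mix_converges():
    config = SimulationConfig(
        n_districts=4, hospitals_per_district=8, threads_per_district=600, seed=9
    )
    study = generate_study(config)
    replies = [m for m in study.messages if m.is_reply]
    assert len(replies) >= 10_000
    n = len(replies)
    for label, p in zip(("positive", "neutral", "negative"), config.sentiment_mix):
        freq = sum(m.sentiment == label for m in replies) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) < 3 * se


def test_gold_mentions_resolve_to_registry(small_study):
    ids = {h.hospital_id for h in small_study.registry}
    message_ids = {m.message_id for m in small_study.messages}
    for mid, gold_set in small_study.gold.mentions.items():
        assert mid in message_ids
        assert gold_set <= ids


def test_allocation_is_strictly_decreasing_on_mentioned_prefix():
    rng = np.random.default_rng(10)
    for _ in range(200):
        n = int(rng.integers(2, 30))
        w = rng.dirichlet(np.ones(n))
        w = np.sort(w)[::-1]
        total = int(rng.integers(0, 400))
        counts = _allocate_counts(w, total)
        assert counts.sum() == (total if total >= 1 else 0)
        positive = counts[counts > 0]
        assert list(positive) == sorted(positive, reverse=True)
        assert len(set(positive)) == len(positive)  # strict, no ties
        # zero counts only in a suffix of the quality ordering
        if len(positive):
            assert (counts[: len(positive)] > 0).all()


def test_noise_increases_with_birthrate_lowers_congruence():
    """200 districts with the default positive birthrate->noise link:
    per-district tau correlates negatively with birthrate."""
    config = SimulationConfig(
        n_districts=200, hospitals_per_district=12, threads_per_district=30, seed=12
    )
    df = simulate_district_study(config)
    sub = df.dropna(subset=["kendall_tau"])
    r = np.corrcoef(sub["birthrate"], sub["kendall_tau"])[0, 1]
    assert r < -0.2


def test_noiseless_district_study_gives_perfect_congruence():
    config = noiseless(
        SimulationConfig(n_districts=20, hospitals_per_district=10, seed=13)
    )
    df = simulate_district_study(config)
    assert np.allclose(df["kendall_tau"], 1.0)
    assert np.allclose(df["spearman_rho"], 1.0)


def test_education_counts_recover_census_moments():
    rng = np.random.default_rng(14)
    counts = sum(simulate_education_counts(5000, rng) for _ in range(50))
    mean, sd = education_stats(list(counts))
    assert abs(mean - 12.39) < 0.15
    assert abs(sd - 3.496) < 0.15
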