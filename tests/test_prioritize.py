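"""Clustering, Regulation Score / Overall Coverage, ranking and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from revex.io import AnnotationTable
from revex.profile_builder import DiseaseProfile
from revex.prioritize import (
    PROFILE_COLUMN_ID,
    RankCriteria,
    ScoreCard,
    cluster_signatures,
    make_scorecards,
    overall_coverage,
    rank_candidates,
    regulation_score,
    reversal_clusters,
)
from revex.reversal_screen import ConcordanceResult, DrugProfile

from conftest import make_signature, random_profile


# ---------------------------------------------------------------------------
# independent per-gene loop oracle for RS / OC
# ---------------------------------------------------------------------------


def naive_rs_oc(profile: DiseaseProfile, drug: DrugProfile) -> tuple[float, float]:
    num = 0.0
    den = 0.0
    a = 0
    for gene, p in profile.entries.items():
        den += abs(p)
        if gene not in drug.lfc:
            continue
        d = drug.lfc[gene]
        if d * p < 0:
            num += abs(d - p) * abs(p)
            a += 1
    return num / den, a / profile.n


def random_drug(rng, profile, missing=0.3) -> DrugProfile:
    lfc = {}
    for g in profile.genes:
        if rng.random() >= missing:
            lfc[g] = float(rng.normal(0, 2))
    lfc = lfc or {profile.genes[0]: 1.0}
    return DrugProfile("d", lfc, 1)


# ---------------------------------------------------------------------------
# RS / OC
# ---------------------------------------------------------------------------


def test_sign_matching_drug_scores_zero(toy_profile):
    drug = DrugProfile("same", dict(toy_profile.entries), 1)
    assert regulation_score(toy_profile, drug) == 0.0
    assert overall_coverage(toy_profile, drug) == 0.0


def test_unit_mirror_scores_two():
    profile = DiseaseProfile({"A": 1.0, "B": -1.0})
    drug = DrugProfile("mirror", {"A": -1.0, "B": 1.0}, 1)
    assert regulation_score(profile, drug) == pytest.approx(2.0)
    assert overall_coverage(profile, drug) == pytest.approx(1.0)


def test_three_gene_worked_example(toy_profile):
    # profile {A:+2, B:-1, C:+1}, drug {A:-1, B:+0.5, C:+3}
    drug = DrugProfile("d", {"A": -1.0, "B": 0.5, "C": 3.0}, 1)
    assert regulation_score(toy_profile, drug) == pytest.approx(1.875)
    assert overall_coverage(toy_profile, drug) == pytest.approx(2 / 3)


def test_mirror_closed_form_on_random_profiles():
    rng = np.random.default_rng(11)
    for _ in range(100):
        profile = random_profile(rng, int(rng.integers(5, 60)))
        p = profile.lfc_vector()
        mirror = DrugProfile("m", {g: -v for g, v in profile.entries.items()}, 1)
        want = 2 * np.sum(p**2) / np.sum(np.abs(p))
        assert regulation_score(profile, mirror) == pytest.approx(want, rel=1e-12)
        assert overall_coverage(profile, mirror) == 1.0


def test_scaled_reverser_closed_form():
    # drug = -alpha * profile (no noise): RS = (1+alpha) * sum p^2 / sum |p|
    rng = np.random.default_rng(12)
    for alpha in (0.25, 0.5, 0.8, 1.0):
        profile = random_profile(rng, 40)
        p = profile.lfc_vector()
        drug = DrugProfile("d", {g: -alpha * v for g, v in profile.entries.items()}, 1)
        want = (1 + alpha) * np.sum(p**2) / np.sum(np.abs(p))
        assert regulation_score(profile, drug) == pytest.approx(want, rel=1e-12)


def test_vectorized_matches_naive_oracle():
    rng = np.random.default_rng(13)
    for _ in range(100):
        profile = random_profile(rng, int(rng.integers(4, 50)))
        drug = random_drug(rng, profile)
        rs_want, oc_want = naive_rs_oc(profile, drug)
        assert regulation_score(profile, drug) == pytest.approx(rs_want, abs=1e-12)
        assert overall_coverage(profile, drug) == pytest.approx(oc_want, abs=1e-12)


def test_zero_drug_lfc_counts_as_not_reversed():
    profile = DiseaseProfile({"A": 2.0})
    drug = DrugProfile("d", {"A": 0.0}, 1)
    assert regulation_score(profile, drug) == 0.0
    assert overall_coverage(profile, drug) == 0.0


def test_empty_drug_profile_warns_not_raises(toy_profile):
    dp = DrugProfile("empty", {}, 1)
    assert regulation_score(toy_profile, dp) == 0.0
    assert overall_coverage(toy_profile, dp) == 0.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_rs_nonnegative_and_zero_iff_nothing_reversed(seed):
    rng = np.random.default_rng(seed)
    profile = random_profile(rng, 15)
    drug = random_drug(rng, profile)
    rs = regulation_score(profile, drug)
    oc = overall_coverage(profile, drug)
    assert rs >= 0.0 and 0.0 <= oc <= 1.0
    assert (rs == 0.0) == (oc == 0.0)


def test_rs_monotone_in_reversal_strength():
    # deepening the reversal of one reversed gene never decreases RS;
    # adding a reversed gene never decreases OC
    profile = DiseaseProfile({"A": 2.0, "B": -1.5, "C": 1.0})
    base = DrugProfile("d", {"A": -0.5, "B": 1.0}, 1)
    deeper = DrugProfile("d", {"A": -2.5, "B": 1.0}, 1)
    extended = DrugProfile("d", {"A": -0.5, "B": 1.0, "C": -0.1}, 1)
    assert regulation_score(profile, deeper) >= regulation_score(profile, base)
    assert overall_coverage(profile, extended) >= overall_coverage(profile, base)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _archetype_columns(profile, n_mirror=4, n_mimic=4, alphas=(0.8, 0.85, 0.9, 1.0)):
    sigs = []
    for i, a in enumerate(alphas[:n_mirror]):
        sigs.append(make_signature(f"mir{i}", {g: -a * v for g, v in profile.entries.items()}))
    for i, a in enumerate(alphas[:n_mimic]):
        sigs.append(make_signature(f"mim{i}", {g: a * v for g, v in profile.entries.items()}))
    return sigs


def test_k_one_puts_everything_together(toy_profile):
    sigs = _archetype_columns(toy_profile)
    asg = cluster_signatures(toy_profile, sigs, k=1, include_profile=True)
    assert {a.cluster for a in asg} == {1}
    assert sum(a.is_profile_column for a in asg) == 1


def test_mirrors_and_mimickers_split_at_k_two():
    profile = random_profile(np.random.default_rng(20), 50)
    sigs = _archetype_columns(profile)
    asg = cluster_signatures(profile, sigs, k=2, include_profile=False)
    clusters = {a.column_id: a.cluster for a in asg}
    mirror_clusters = {clusters[f"mir{i}"] for i in range(4)}
    mimic_clusters = {clusters[f"mim{i}"] for i in range(4)}
    assert len(mirror_clusters) == 1 and len(mimic_clusters) == 1
    assert mirror_clusters != mimic_clusters


def test_relabeling_preserves_partition():
    profile = random_profile(np.random.default_rng(21), 30)
    sigs = _archetype_columns(profile)
    asg1 = cluster_signatures(profile, sigs, k=2, include_profile=False)
    renamed = [make_signature("z" + s.signature_id, s.lfc) for s in sigs]
    asg2 = cluster_signatures(profile, renamed, k=2, include_profile=False)
    part1 = {}
    for a in asg1:
        part1.setdefault(a.cluster, set()).add(a.column_id)
    part2 = {}
    for a in asg2:
        part2.setdefault(a.cluster, set()).add(a.column_id.removeprefix("z"))
    assert set(map(frozenset, part1.values())) == set(map(frozenset, part2.values()))


def test_k_larger_than_columns_is_an_error(toy_profile):
    sigs = _archetype_columns(toy_profile)[:2]
    with pytest.raises(ValueError, match="k="):
        cluster_signatures(toy_profile, sigs, k=10, include_profile=False)


def test_zero_overlap_column_uses_max_distance_rule(toy_profile):
    sigs = _archetype_columns(toy_profile, n_mirror=2, n_mimic=2)
    sigs.append(make_signature("nohit", {"ZZZ": 1.0}))
    asg = cluster_signatures(toy_profile, sigs, k=2, include_profile=False)
    assert any(a.column_id == "nohit" for a in asg)


def test_reversal_cluster_detection():
    asg = [
        type("A", (), {"column_id": s, "cluster": c, "is_profile_column": False})()
        for s, c in [("s1", 1), ("s2", 1), ("s3", 2), ("s4", 2)]
    ]
    conc = [
        ConcordanceResult("s1", "d1", "l", -0.8, 20, True),
        ConcordanceResult("s2", "d1", "l", -0.7, 20, True),
        ConcordanceResult("s3", "d2", "l", 0.5, 20, False),
        ConcordanceResult("s4", "d2", "l", 0.4, 20, False),
    ]
    assert reversal_clusters(asg, conc, cutoff=-0.2) == {1}


# ---------------------------------------------------------------------------
# ranking and filters
# ---------------------------------------------------------------------------


def _annotations(rows: dict[str, tuple[float, int]]) -> AnnotationTable:
    df = pd.DataFrame(
        {
            "bbb": [b for b, _ in rows.values()],
            "n_trials": [t for _, t in rows.values()],
            "indication": ["x"] * len(rows),
        },
        index=pd.Index(list(rows), name="drug"),
    )
    return AnnotationTable(df)


def card(drug, rs, oc, in_rev=True):
    return ScoreCard(drug, rs, oc, cluster=1, in_reversal_cluster=in_rev)


def test_rank_order_and_filters():
    ann = _annotations({"d1": (0.95, 0), "d2": (0.95, 0)})
    ranked = rank_candidates([card("d2", 1.0, 0.5), card("d1", 2.0, 0.5)], ann)
    assert [(c.drug, c.rank) for c in ranked] == [("d1", 1), ("d2", 2)]
    assert all(c.passes_filters for c in ranked)


def test_top_rs_with_prior_trial_keeps_rank_but_fails_filters():
    # mirrors the exclusion of a top-scoring drug already tried in trials
    ann = _annotations({"top": (0.99, 1), "runner": (0.95, 0)})
    ranked = rank_candidates([card("top", 2.093, 0.61), card("runner", 1.653, 0.601)], ann)
    assert ranked[0].drug == "top" and ranked[0].rank == 1
    assert not ranked[0].passes_filters
    assert ranked[1].passes_filters


def test_bbb_boundary_is_inclusive_at_min():
    ann = _annotations({"lo": (0.89, 0), "at": (0.90, 0)})
    ranked = rank_candidates([card("lo", 2.0, 0.5), card("at", 1.0, 0.5)], ann)
    by = {c.drug: c for c in ranked}
    assert not by["lo"].passes_filters
    assert by["at"].passes_filters


def test_rs_and_oc_rankings_may_disagree():
    # a drug can reverse more genes (higher OC) yet score lower RS
    profile = DiseaseProfile({"A": 3.0, "B": -2.0, "C": 1.0, "D": -1.0})
    strong_narrow = DrugProfile("narrow", {"A": -4.0, "B": 4.0}, 1)
    weak_broad = DrugProfile("broad", {"A": -0.1, "B": 0.1, "C": -0.1, "D": 0.1}, 1)
    rs_n = regulation_score(profile, strong_narrow)
    rs_b = regulation_score(profile, weak_broad)
    assert rs_n > rs_b
    assert overall_coverage(profile, weak_broad) > overall_coverage(profile, strong_narrow)


def test_missing_annotation_fails_filters_not_run():
    ann = _annotations({"known": (0.95, 0)})
    ranked = rank_candidates([card("known", 1.0, 0.5), card("ghost", 2.0, 0.9)], ann)
    by = {c.drug: c for c in ranked}
    assert by["ghost"].rank == 1 and not by["ghost"].passes_filters
    assert by["known"].passes_filters


def test_require_reversal_cluster_filter():
    ann = _annotations({"in": (0.95, 0), "out": (0.95, 0)})
    cards = [card("in", 1.0, 0.5, in_rev=True), card("out", 2.0, 0.5, in_rev=False)]
    strict = {c.drug: c for c in rank_candidates(cards, ann)}
    assert not strict["out"].passes_filters
    lax = {c.drug: c for c in rank_candidates(
        cards, ann, RankCriteria(require_reversal_cluster=False))}
    assert lax["out"].passes_filters


def test_empty_scores_error():
    with pytest.raises(ValueError):
        rank_candidates([], _annotations({"d": (0.5, 0)}))


def test_make_scorecards_attaches_clusters():
    profile = DiseaseProfile({"A": 2.0, "B": -1.0})
    dps = [DrugProfile("d1", {"A": -2.0, "B": 1.0}, 2)]
    asg = [
        type("A", (), {"column_id": "s1", "cluster": 1, "is_profile_column": False})(),
        type("A", (), {"column_id": "s2", "cluster": 1, "is_profile_column": False})(),
        type("A", (), {"column_id": PROFILE_COLUMN_ID, "cluster": 2,
                       "is_profile_column": True})(),
    ]
    conc = [
        ConcordanceResult("s1", "d1", "l", -0.9, 2, True),
        ConcordanceResult("s2", "d1", "l", -0.8, 2, True),
    ]
    (c,) = make_scorecards(profile, dps, asg, conc)
    assert c.cluster == 1 and c.in_reversal_cluster
    assert c.rs == pytest.approx(regulation_score(profile, dps[0]))
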