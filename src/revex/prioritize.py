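"""Signature clustering, Regulation Score / Overall Coverage, and ranking.

The Regulation Score of a drug against a disease profile of n genes is

    RS = [ Σ_k Δ_k · |LFC_k^disease| ] / [ Σ_{i=1..n} |LFC_i^disease| ]

with Δ_k = |LFC_k^drug − LFC_k^disease| when the drug moves gene k against
its disease direction (the two LFCs have opposite signs) and Δ_k = 0
otherwise — including when the gene is unmeasured in the drug profile or the
drug LFC is exactly 0. RS is nonnegative, 0 exactly when nothing is
reversed; for the exact mirror drug (drug LFC = −disease LFC) it closes to
2·Σ LFC² / Σ|LFC|.

The Overall Coverage is the fraction of profile genes the drug reverses:
OC = a/g with a the count of opposite-sign genes and g the profile size.
Unmeasured genes count toward g but never toward a.

Signatures (and optionally the profile itself as one extra column) are also
clustered with Ward agglomeration over Minkowski-p distances computed on
pairwise-complete genes and rescaled to the full profile length, so that two
sparsely-overlapping columns are not spuriously close.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import AnnotationTable, Signature
from .profile_builder import DiseaseProfile
from .reversal_screen import ConcordanceResult, DrugProfile

log = logging.getLogger(__name__)

PROFILE_COLUMN_ID = "DISEASE_PROFILE"


@dataclass
class ClusterAssignment:
    column_id: str
    cluster: int
    is_profile_column: bool = False


@dataclass
class ScoreCard:
    drug: str
    rs: float
    oc: float
    cluster: int
    in_reversal_cluster: bool
    rank: int = 0
    passes_filters: bool = False


@dataclass(frozen=True)
class RankCriteria:
    bbb_min: float = 0.9
    require_no_trials: bool = True
    require_reversal_cluster: bool = True


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_signatures(
    profile: DiseaseProfile,
    sigs: Sequence[Signature],
    k: int = 8,
    minkowski_p: float = 2.0,
    include_profile: bool = True,
) -> list[ClusterAssignment]:
    """Ward clustering of signature columns restricted to profile genes.

    Pairwise Minkowski-p distance over pairwise-complete genes, rescaled by
    (g/m)^(1/p) where m is the number of complete pairs; a pair with no
    complete gene gets the maximum observed distance. Column order (hence
    the dendrogram and tie-breaks) is fixed by sorting column ids, so the
    partition is deterministic.
    """
    if minkowski_p < 1:
        raise ValueError(f"minkowski_p must be >= 1, got {minkowski_p}")
    genes = profile.genes
    g = len(genes)
    columns: dict[str, np.ndarray] = {}
    for sig in sigs:
        vec = np.full(g, np.nan)
        for i, gene in enumerate(genes):
            if gene in sig.lfc:
                vec[i] = sig.lfc[gene]
        if np.isnan(vec).all():
            log.warning(
                "signature %s shares no gene with the profile; distances fall "
                "back to the max-distance rule", sig.signature_id,
            )
        columns[sig.signature_id] = vec
    if include_profile:
        if PROFILE_COLUMN_ID in columns:
            raise ValueError(f"column id {PROFILE_COLUMN_ID!r} is reserved")
        columns[PROFILE_COLUMN_ID] = profile.lfc_vector()
    ids = sorted(columns)
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n} columns]")

    X = np.stack([columns[c] for c in ids])  # columns × genes
    finite = np.isfinite(X)
    D = np.zeros((n, n))
    empty_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = finite[i] & finite[j]
            m = int(mask.sum())
            if m == 0:
                empty_pairs.append((i, j))
                continue
            s = np.sum(np.abs(X[i, mask] - X[j, mask]) ** minkowski_p)
            D[i, j] = D[j, i] = (s * g / m) ** (1.0 / minkowski_p)
    if empty_pairs:
        dmax = D.max()
        for i, j in empty_pairs:
            D[i, j] = D[j, i] = dmax

    if n == 1:
        labels = np.array([1])
    else:
        Z = linkage(squareform(D, checks=False), method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
    return [
        ClusterAssignment(cid, int(lab), cid == PROFILE_COLUMN_ID)
        for cid, lab in zip(ids, labels)
    ]


def reversal_clusters(
    assignments: Sequence[ClusterAssignment],
    concordances: Sequence[ConcordanceResult],
    cutoff: float = -0.2,
) -> set[int]:
    """Clusters whose member signatures have median concordance < cutoff.

    Operationalizes the visual identification of reversal clusters in a
    clustered heatmap; the profile column is excluded from the medians."""
    r_by_sig = {c.signature_id: c.r for c in concordances}
    members: dict[int, list[float]] = {}
    for a in assignments:
        if a.is_profile_column:
            continue
        r = r_by_sig.get(a.column_id)
        if r is not None and np.isfinite(r):
            members.setdefault(a.cluster, []).append(r)
    return {cl for cl, rs in members.items() if np.median(rs) < cutoff}


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _aligned(profile: DiseaseProfile, drug: DrugProfile) -> tuple[np.ndarray, np.ndarray]:
    p = profile.lfc_vector()
    d = np.array([drug.lfc.get(g, np.nan) for g in profile.genes])
    return p, d


def regulation_score(profile: DiseaseProfile, drug: DrugProfile) -> float:
    """Regulation Score (see module docstring). Nonnegative; 0 when the drug
    reverses no profile gene. An empty drug profile scores 0 with a warning."""
    if profile.n == 0:
        raise ValueError("profile must be non-empty")
    if not drug.lfc:
        log.warning("drug %s has an empty profile; RS = 0", drug.drug)
        return 0.0
    p, d = _aligned(profile, drug)
    reversed_ = np.isfinite(d) & (d * p < 0)
    delta = np.where(reversed_, np.abs(d - p), 0.0)
    return float(np.sum(delta * np.abs(p)) / np.sum(np.abs(p)))


def overall_coverage(profile: DiseaseProfile, drug: DrugProfile) -> float:
    """Fraction of profile genes the drug reverses (opposite LFC sign);
    unmeasured genes count in the denominator only."""
    if profile.n == 0:
        raise ValueError("profile must be non-empty")
    if not drug.lfc:
        log.warning("drug %s has an empty profile; OC = 0", drug.drug)
        return 0.0
    p, d = _aligned(profile, drug)
    a = int(np.sum(np.isfinite(d) & (d * p < 0)))
    return a / profile.n


# ---------------------------------------------------------------------------
# scorecards and ranking
# ---------------------------------------------------------------------------


def make_scorecards(
    profile: DiseaseProfile,
    drug_profiles: Sequence[DrugProfile],
    assignments: Sequence[ClusterAssignment] = (),
    concordances: Sequence[ConcordanceResult] = (),
    reversal_cutoff: float = -0.2,
) -> list[ScoreCard]:
    """Score every drug and attach its cluster membership.

    A drug's cluster is the most common cluster among its signatures
    (smallest id on ties); ``in_reversal_cluster`` is true when any of its
    signatures sits in a reversal cluster. Without cluster input both fields
    are neutral (cluster 0, flag True) so ranking can run standalone.
    """
    rev = reversal_clusters(assignments, concordances, reversal_cutoff) if assignments else set()
    sig_cluster = {a.column_id: a.cluster for a in assignments if not a.is_profile_column}
    sig_drug = {c.signature_id: c.perturbagen for c in concordances}
    drug_clusters: dict[str, list[int]] = {}
    for sid, cl in sig_cluster.items():
        drug = sig_drug.get(sid)
        if drug is not None:
            drug_clusters.setdefault(drug, []).append(cl)
    cards = []
    for dp in drug_profiles:
        clusters = drug_clusters.get(dp.drug, [])
        if clusters:
            counts = {c: clusters.count(c) for c in set(clusters)}
            best = max(counts.values())
            cluster = min(c for c, ct in counts.items() if ct == best)
            in_rev = bool(set(clusters) & rev)
        else:
            cluster, in_rev = 0, True
        cards.append(
            ScoreCard(
                drug=dp.drug,
                rs=regulation_score(profile, dp),
                oc=overall_coverage(profile, dp),
                cluster=cluster,
                in_reversal_cluster=in_rev,
            )
        )
    return cards


def rank_candidates(
    scores: Sequence[ScoreCard],
    annotations: AnnotationTable,
    criteria: RankCriteria = RankCriteria(),
) -> list[ScoreCard]:
    """Rank by RS (descending; ties by OC then drug id) and apply the
    candidate filters: BBB ≥ bbb_min, no prior disease trials, membership in
    a reversal cluster. Filters never change the rank order — a top-RS drug
    that fails a filter keeps its rank but is flagged out."""
    scores = list(scores)
    if not scores:
        raise ValueError("empty score list")
    ranked = sorted(scores, key=lambda c: (-c.rs, -c.oc, c.drug))
    out = []
    for i, card in enumerate(ranked, start=1):
        ann = annotations.get(card.drug)
        if ann is None:
            log.warning("drug %s missing from annotations; fails filters", card.drug)
            passes = False
        else:
            bbb_ok = bool(np.isfinite(ann["bbb"]) and ann["bbb"] >= criteria.bbb_min)
            trials_ok = (not criteria.require_no_trials) or ann["n_trials"] == 0
            cluster_ok = (not criteria.require_reversal_cluster) or card.in_reversal_cluster
            passes = bbb_ok and trials_ok and cluster_ok
        out.append(
            ScoreCard(
                drug=card.drug,
                rs=card.rs,
                oc=card.oc,
                cluster=card.cluster,
                in_reversal_cluster=card.in_reversal_cluster,
                rank=i,
                passes_filters=passes,
            )
        )
    return out
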