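"""Concordance screening of signatures against the disease profile.

The concordance of a signature is the Pearson correlation between the
disease-profile LFCs and the signature LFCs over their shared genes; a
negative value means the perturbation moves disease genes against their
disease direction. A signature passes when its concordance is strictly below
its library's (negative) cutoff and it overlaps the profile on at least
``min_overlap`` genes — the overlap floor guards against the inflated
correlations of sparse-overlap libraries.

Passing signatures are aggregated to one profile per drug: for each gene,
the median LFC over the drug's passing signatures in which the gene was
measured (a gene absent everywhere stays absent — unmeasured is not zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Signature, SignatureSet
from .profile_builder import DiseaseProfile

log = logging.getLogger(__name__)

MIN_OVERLAP_DEFAULT = 10


@dataclass
class ConcordanceResult:
    signature_id: str
    perturbagen: str
    library: str
    r: float  # NaN = flagged (insufficient overlap or zero variance)
    n_overlap: int
    passed: bool

    @property
    def flagged(self) -> bool:
        return math.isnan(self.r)


@dataclass
class DrugProfile:
    """Per-drug gene → median-LFC aggregate over its passing signatures."""

    drug: str
    lfc: dict[str, float]
    n_signatures: int

    def __post_init__(self) -> None:
        if self.n_signatures < 1:
            raise ValueError("a DrugProfile needs >=1 contributing signature")


def concordance(
    profile: DiseaseProfile, sig: Signature, min_overlap: int = MIN_OVERLAP_DEFAULT
) -> ConcordanceResult:
    """Pearson r between profile and signature over shared genes.

    Flagged (r = NaN, passed False) when fewer than ``min_overlap`` genes are
    shared or either vector is constant on the overlap. Never raises: a
    screen must not abort on one bad signature. ``passed`` is always False
    here — the library cutoff is applied by :func:`screen`.
    """
    if min_overlap < 3:
        raise ValueError(f"min_overlap must be >= 3, got {min_overlap}")
    shared = [g for g in profile.entries if g in sig.lfc]
    n = len(shared)
    if n < min_overlap:
        return ConcordanceResult(sig.signature_id, sig.perturbagen, sig.library, float("nan"), n, False)
    x = np.array([profile.entries[g] for g in shared])
    y = np.array([sig.lfc[g] for g in shared])
    if x.std() == 0 or y.std() == 0:
        return ConcordanceResult(sig.signature_id, sig.perturbagen, sig.library, float("nan"), n, False)
    r = float(np.corrcoef(x, y)[0, 1])
    return ConcordanceResult(sig.signature_id, sig.perturbagen, sig.library, r, n, False)


def screen(
    profile: DiseaseProfile,
    sigs: SignatureSet,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> list[ConcordanceResult]:
    """Score every signature and apply its library's cutoff (strict <).

    Results are sorted ascending by r (flagged rows last, ties by signature
    id); per-library pass counts are logged for the library-accounting table.
    """
    libraries = {s.library for s in sigs.signatures}
    missing = libraries - set(sigs.library_cutoffs)
    if missing:
        raise ValueError(f"no cutoff for library {sorted(missing)[0]!r}")
    results = []
    for sig in sigs.signatures:
        res = concordance(profile, sig, min_overlap)
        if not res.flagged and res.r < sigs.library_cutoffs[sig.library]:
            res.passed = True
        results.append(res)
    results.sort(key=lambda c: (c.flagged, c.r if not c.flagged else 0.0, c.signature_id))
    for lib, counts in library_counts(results).iterrows():
        log.info(
            "library %s: %d/%d signatures passed, %d chemicals",
            lib, counts["passed"], counts["signatures"], counts["chemicals"],
        )
    return results


def library_counts(results: Sequence[ConcordanceResult]) -> pd.DataFrame:
    """Per-library accounting: signatures scored/passed and unique
    perturbagens among the passers."""
    rows = {}
    for lib in sorted({c.library for c in results}):
        here = [c for c in results if c.library == lib]
        passed = [c for c in here if c.passed]
        rows[lib] = {
            "signatures": len(here),
            "passed": len(passed),
            "chemicals": len({c.perturbagen for c in passed}),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def aggregate_drug(
    passing: Iterable[tuple[Signature, ConcordanceResult]]
) -> list[DrugProfile]:
    """Median-aggregate passing signatures per perturbagen.

    Per gene the median runs over the signatures of that drug in which the
    gene is present; a gene measured in none of them is absent from the
    drug's profile. Empty input yields an empty list (not an error).
    """
    by_drug: dict[str, list[Signature]] = {}
    for sig, res in passing:
        if not res.passed:
            raise ValueError(
                f"aggregate_drug got non-passing signature {sig.signature_id!r}"
            )
        by_drug.setdefault(sig.perturbagen, []).append(sig)
    out = []
    for drug in sorted(by_drug):
        sigs = by_drug[drug]
        genes = sorted({g for s in sigs for g in s.lfc})
        lfc = {
            g: float(np.median([s.lfc[g] for s in sigs if g in s.lfc])) for g in genes
        }
        out.append(DrugProfile(drug, lfc, len(sigs)))
    return out
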