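"""Disease expression profile from the two DE layers.

The profile is the set of genes called significant in *both* the transcript
and the protein layer, each carrying its transcript-layer log2 fold change
(protein LFCs, including imputed ones, are kept only as metadata). With
``concordant_only`` the two layers must additionally agree in direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .diffexpr import DERecord


@dataclass(frozen=True)
class DiseaseProfile:
    """Ordered gene → log2-fold-change map, ascending LFC.

    ``n`` (the profile size) is the denominator of the coverage index; the
    per-gene LFC magnitudes weight the regulation score.
    """

    entries: Mapping[str, float]
    protein_lfc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("disease profile must be non-empty")
        vals = list(self.entries.values())
        if any(v == 0 for v in vals):
            gene = next(g for g, v in self.entries.items() if v == 0)
            raise ValueError(f"profile gene {gene!r} has zero LFC")
        ordered = dict(sorted(self.entries.items(), key=lambda kv: (kv[1], kv[0])))
        object.__setattr__(self, "entries", ordered)

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def lfc_vector(self) -> np.ndarray:
        return np.array(list(self.entries.values()))


class EmptyIntersectionError(ValueError):
    """No gene is significant in both layers; the pipeline cannot proceed."""

    def __init__(self, n_rna: int, n_protein: int, concordant_only: bool):
        self.n_rna = n_rna
        self.n_protein = n_protein
        extra = " after requiring direction concordance" if concordant_only else ""
        super().__init__(
            f"empty intersection of significant sets{extra} "
            f"({n_rna} rna-significant, {n_protein} protein-significant)"
        )


def build_profile(
    rna: Iterable[DERecord],
    protein: Iterable[DERecord],
    concordant_only: bool = False,
) -> DiseaseProfile:
    """Intersect the significant sets of the two layers into a profile.

    The stored value per gene is the rna-layer LFC. ``concordant_only``
    additionally requires sign(rna LFC) == sign(protein LFC) — imputed
    protein LFCs carry the sign of their detected group and participate in
    the check like any other.
    """
    rna = list(rna)
    protein = list(protein)
    if not rna or not protein:
        raise ValueError("both DE record lists must be non-empty")
    rna_sig = {r.feature_id: r for r in rna if r.significant}
    prot_sig = {r.feature_id: r for r in protein if r.significant}
    entries: dict[str, float] = {}
    prot_meta: dict[str, float] = {}
    for gene, rrec in rna_sig.items():
        prec = prot_sig.get(gene)
        if prec is None:
            continue
        if concordant_only and np.sign(rrec.lfc) != np.sign(prec.lfc):
            continue
        entries[gene] = rrec.lfc
        prot_meta[gene] = prec.lfc
    if not entries:
        raise EmptyIntersectionError(len(rna_sig), len(prot_sig), concordant_only)
    return DiseaseProfile(entries, prot_meta)
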