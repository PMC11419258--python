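"""Synthetic inputs with planted ground truth.

Generates every input the pipeline consumes: a negative-binomial case/control
count matrix with planted differentially expressed genes, a log-normal
proteome intensity matrix with structural detection dropout (one-group-only
proteins), a perturbagen signature library mixing three drug archetypes —
*reversers* (signature anti-correlated with the disease profile), *mimickers*
(correlated) and *neutrals* (uncorrelated noise) — and a per-drug annotation
table (blood–brain-barrier permeation probability, prior trial count,
approved indication).

Every generator is a pure function of its config: a single integer seed is
expanded into independent per-stage substreams, so stages can be regenerated
independently and changing, say, the sample size of one layer does not move
the planted truth shared by both layers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationTable, CountMatrix, IntensityMatrix, Signature, SignatureSet

ARCHETYPES = ("reverser", "mimicker", "neutral")

# substream ids: stable keys into the seed expansion
_STREAM = {"plant": 0, "counts": 1, "intensities": 2, "signatures": 3, "annotations": 4}


class ConfigError(ValueError):
    """An invalid SimConfig field; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort and signature library.

    Defaults emulate a desk-scale version of a tumor/control bulk design:
    a few thousand genes, ~10% planted DE genes with |log2FC| between 1.5
    and 4, negative-binomial counts with moderate dispersion, a pooled-sample
    proteome with low technical noise and structural dropout, and a library
    dominated by neutral drugs with a minority of reversers and mimickers.
    """

    n_genes: int = 2000
    n_case: int = 20
    n_control: int = 20
    frac_de: float = 0.1
    lfc_range: tuple[float, float] = (1.5, 4.0)
    nb_dispersion: float = 0.05
    base_mean_log_mu: float = 5.0
    base_mean_log_sd: float = 1.5
    dropout_rate: float = 0.2
    intensity_noise_sd: float = 0.1  # log2-scale measurement SD (pooled samples)
    n_drugs: int = 50
    sigs_per_drug: int = 3
    archetype_mix: tuple[float, float, float] = (0.1, 0.1, 0.8)
    alpha_range: tuple[float, float] = (0.6, 1.0)
    noise_sd: float = 0.3
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(name: str, why: str):
            return ConfigError(f"invalid SimConfig.{name}: {why}")

        for name in ("n_genes", "n_case", "n_control", "n_drugs", "sigs_per_drug"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise bad(name, f"must be a positive integer, got {v!r}")
        for name in ("frac_de", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise bad(name, f"must be in [0,1], got {v!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise bad("missing_rate", f"must be in [0,1), got {self.missing_rate!r}")
        lo, hi = self.lfc_range
        if not (0 < lo <= hi):
            raise bad("lfc_range", f"need 0 < min <= max, got {self.lfc_range!r}")
        if not self.nb_dispersion > 0:
            raise bad("nb_dispersion", f"must be positive, got {self.nb_dispersion!r}")
        for name in ("noise_sd", "intensity_noise_sd"):
            if getattr(self, name) < 0:
                raise bad(name, "must be nonnegative")
        mix = self.archetype_mix
        if len(mix) != 3 or any(m < 0 for m in mix):
            raise bad("archetype_mix", f"need three nonnegative fractions, got {mix!r}")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise bad("archetype_mix", f"must sum to 1 within 1e-9, got sum {sum(mix)!r}")
        alo, ahi = self.alpha_range
        if not (0 < alo <= ahi <= 1):
            raise bad("alpha_range", f"need 0 < min <= max <= 1, got {self.alpha_range!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one stage of the simulation."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAM[stream],))
        return np.random.default_rng(ss)


@dataclass
class TruthTable:
    """Planted ground truth: DE genes shared by both omics layers and the
    archetype (with reversal/mimicry strength alpha) of every drug."""

    de_genes: dict[str, float] = field(default_factory=dict)
    drug_archetypes: dict[str, tuple[str, float | None]] = field(default_factory=dict)

    def drugs_of(self, archetype: str) -> list[str]:
        return sorted(d for d, (a, _) in self.drug_archetypes.items() if a == archetype)


def gene_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def planted_truth(config: SimConfig) -> TruthTable:
    """Draw the shared DE-gene truth (which genes, which log2FC, which sign).

    Depends only on (seed, n_genes, frac_de, lfc_range): resizing a layer's
    cohort never moves the planted genes, so the transcriptome and proteome
    configs derived from one seed plant the same effects.
    """
    rng = config.rng("plant")
    genes = gene_ids(config)
    n_de = int(round(config.frac_de * config.n_genes))
    chosen = rng.choice(config.n_genes, size=n_de, replace=False)
    lo, hi = config.lfc_range
    mags = rng.uniform(lo, hi, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    de = {genes[i]: s * m for i, s, m in zip(sorted(chosen), signs, mags)}
    return TruthTable(de_genes=de)


# ---------------------------------------------------------------------------
# transcriptome counts
# ---------------------------------------------------------------------------


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, TruthTable]:
    """Negative-binomial gene × sample counts with planted DE genes.

    Per-gene control mean is log-normal; planted genes have their case mean
    shifted by 2**lfc. NB is parameterized by (mean m, dispersion d) with
    variance m + d·m², the structure bulk RNA-seq DE methods assume.
    """
    truth = planted_truth(config)
    rng = config.rng("counts")
    genes = gene_ids(config)
    base = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sd, config.n_genes)
    shift = np.array([2.0 ** truth.de_genes.get(g, 0.0) for g in genes])
    mean_case = base * shift
    mean_ctrl = base

    d = config.nb_dispersion
    size = 1.0 / d  # NB "number of successes"

    def draw(means: np.ndarray, n: int) -> np.ndarray:
        p = size / (size + means)
        return rng.negative_binomial(size, p[:, None], size=(config.n_genes, n))

    case = draw(mean_case, config.n_case)
    ctrl = draw(mean_ctrl, config.n_control)
    samples = [f"case_{i + 1}" for i in range(config.n_case)] + [
        f"ctrl_{i + 1}" for i in range(config.n_control)
    ]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=samples)
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return CountMatrix(values, groups), truth


# ---------------------------------------------------------------------------
# proteome intensities
# ---------------------------------------------------------------------------


def simulate_intensities(config: SimConfig) -> tuple[IntensityMatrix, TruthTable]:
    """Log-normal protein × sample intensities with structural dropout.

    A ``dropout_rate`` fraction of the planted DE proteins is made
    one-group-only: every sample of the low-abundance group is set to 0
    (not detected), which is exactly the case the imputed-LFC rule in the
    differential-expression stage exists for.
    """
    truth = planted_truth(config)
    rng = config.rng("intensities")
    genes = gene_ids(config)
    base = rng.lognormal(config.base_mean_log_mu + 6.0, config.base_mean_log_sd, config.n_genes)
    lfc = np.array([truth.de_genes.get(g, 0.0) for g in genes])
    mean_case = base * np.power(2.0, lfc)
    mean_ctrl = base

    noise_ln = config.intensity_noise_sd * np.log(2.0)  # log2 SD -> natural-log SD

    def draw(means: np.ndarray, n: int) -> np.ndarray:
        return means[:, None] * np.exp(
            rng.normal(0.0, noise_ln, size=(config.n_genes, n))
        )

    case = draw(mean_case, config.n_case)
    ctrl = draw(mean_ctrl, config.n_control)

    de_idx = [i for i, g in enumerate(genes) if g in truth.de_genes]
    n_drop = int(round(config.dropout_rate * len(de_idx)))
    if n_drop:
        dropped = rng.choice(len(de_idx), size=n_drop, replace=False)
        for j in dropped:
            i = de_idx[j]
            if lfc[i] > 0:  # up in case: control group below detection
                ctrl[i, :] = 0.0
            else:
                case[i, :] = 0.0

    samples = [f"case_{i + 1}" for i in range(config.n_case)] + [
        f"ctrl_{i + 1}" for i in range(config.n_control)
    ]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=samples)
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return IntensityMatrix(values, groups), truth


# ---------------------------------------------------------------------------
# signature library
# ---------------------------------------------------------------------------


def drug_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_drugs))
    return [f"drug_{i:0{width}d}" for i in range(1, config.n_drugs + 1)]


def _assign_archetypes(config: SimConfig, rng: np.random.Generator) -> TruthTable:
    drugs = drug_ids(config)
    n_rev = int(round(config.archetype_mix[0] * config.n_drugs))
    n_mim = int(round(config.archetype_mix[1] * config.n_drugs))
    n_rev = min(n_rev, config.n_drugs)
    n_mim = min(n_mim, config.n_drugs - n_rev)
    labels = (
        ["reverser"] * n_rev
        + ["mimicker"] * n_mim
        + ["neutral"] * (config.n_drugs - n_rev - n_mim)
    )
    order = rng.permutation(config.n_drugs)
    truth = TruthTable()
    alo, ahi = config.alpha_range
    for pos, drug_i in enumerate(order):
        label = labels[pos]
        alpha = float(rng.uniform(alo, ahi)) if label != "neutral" else None
        truth.drug_archetypes[drugs[drug_i]] = (label, alpha)
    return truth


def simulate_signature_library(
    profile, config: SimConfig
) -> tuple[SignatureSet, TruthTable]:
    """Per-drug perturbation signatures over the disease-profile genes.

    reverser:  lfc_g = −alpha · profile_g + N(0, noise_sd)
    mimicker:  lfc_g = +alpha · profile_g + N(0, noise_sd)
    neutral:   lfc_g =  N(0, noise_sd)            (pure noise, uncorrelated)

    then a ``missing_rate`` fraction of each signature's genes is masked out
    (absent keys, emulating partial gene coverage of real libraries).
    """
    if profile.n == 0:
        raise ValueError("cannot simulate signatures from an empty profile")
    rng = config.rng("signatures")
    truth = _assign_archetypes(config, rng)
    genes = list(profile.entries)
    pvec = np.array([profile.entries[g] for g in genes])
    g = len(genes)
    n_miss = int(round(config.missing_rate * g))

    sigs: list[Signature] = []
    for drug in drug_ids(config):
        label, alpha = truth.drug_archetypes[drug]
        for j in range(config.sigs_per_drug):
            noise = rng.normal(0.0, config.noise_sd, size=g) if config.noise_sd > 0 else np.zeros(g)
            if label == "reverser":
                vec = -alpha * pvec + noise
            elif label == "mimicker":
                vec = alpha * pvec + noise
            else:
                vec = noise
            keep = np.ones(g, dtype=bool)
            if n_miss:
                keep[rng.choice(g, size=n_miss, replace=False)] = False
            lfc = {genes[i]: float(vec[i]) for i in range(g) if keep[i]}
            sigs.append(Signature(f"{drug}_sig{j + 1}", drug, "synthetic", lfc))
    sigset = SignatureSet(sigs, {"synthetic": -0.2})
    return sigset, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_INDICATIONS = (
    "hypertension",
    "bacterial infection",
    "fungal infection",
    "epilepsy",
    "depression",
    "rheumatoid arthritis",
    "type 2 diabetes",
    "asthma",
    "leukemia",
    "breast cancer",
)


def simulate_annotations(
    drugs: Sequence[str],
    config: SimConfig,
    overrides: Mapping[str, Mapping[str, object]] | None = None,
) -> AnnotationTable:
    """Per-drug BBB probability, prior disease-trial count and indication.

    BBB is Beta(5, 1.5)-distributed (most marketed small molecules score
    high), trial counts are Poisson(0.5) (most drugs untried for the
    disease), indications are drawn from a fixed list. ``overrides`` forces
    specific fields for named drugs, e.g. to pin a known candidate.
    """
    drugs = list(drugs)
    if not drugs:
        raise ValueError("drug list must be non-empty")
    if len(set(drugs)) != len(drugs):
        dup = next(d for i, d in enumerate(drugs) if d in drugs[:i])
        raise ValueError(f"duplicate drug id {dup!r}")
    rng = config.rng("annotations")
    bbb = rng.beta(5.0, 1.5, size=len(drugs))
    n_trials = rng.poisson(0.5, size=len(drugs))
    indication = rng.choice(_INDICATIONS, size=len(drugs))
    df = pd.DataFrame(
        {"bbb": bbb, "n_trials": n_trials, "indication": indication},
        index=pd.Index(drugs, name="drug"),
    )
    if overrides:
        for drug, fields in overrides.items():
            if drug not in df.index:
                raise ValueError(f"override for unknown drug {drug!r}")
            for key, val in fields.items():
                if key not in df.columns:
                    raise ValueError(f"override for unknown field {key!r}")
                df.loc[drug, key] = val
    return AnnotationTable(df)
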