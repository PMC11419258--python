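"""Sample QC and per-layer differential expression.

Transcripts: median-of-ratios size-factor normalization, log2 fold change of
group means, per-gene Welch two-sample test on log2(normalized + pseudocount),
Benjamini–Hochberg adjustment. A gene is DE when adjusted p < alpha and
|LFC| > lfc_min.

Proteins: plain log2 ratio of raw group mean intensities, Welch test on
log2(intensity + pseudocount), Bonferroni adjustment. Proteins detected in
only one group (zero mean in the other) have no finite ratio; their LFC is
imputed to ±L_max, the largest finite |LFC| observed among two-group proteins
(or a configured override), signed toward the detected group, and they count
as significant on the adjusted p-value alone.

Sample QC flags outliers by PCA on log2(value + pseudocount): a sample whose
Euclidean distance to its own group centroid in the leading component scores
exceeds mean + k·SD of its group's distances is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, IntensityMatrix, _LabeledMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEConfig:
    alpha: float = 0.05
    lfc_min: float = 1.0
    rna_adjust: Literal["benjamini_hochberg"] = "benjamini_hochberg"
    protein_adjust: Literal["bonferroni"] = "bonferroni"
    pseudocount: float = 1.0
    impute_lfc_policy: Literal["max_observed"] = "max_observed"
    l_max_override: float | None = None
    pca_components: int = 2
    outlier_k_sd: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not self.lfc_min > 0:
            raise ValueError(f"lfc_min must be positive, got {self.lfc_min}")
        if not self.pseudocount > 0:
            raise ValueError(f"pseudocount must be positive, got {self.pseudocount}")
        if self.pca_components < 2:
            raise ValueError(f"pca_components must be >= 2, got {self.pca_components}")
        if not self.outlier_k_sd > 0:
            raise ValueError(f"outlier_k_sd must be positive, got {self.outlier_k_sd}")


@dataclass
class DERecord:
    """One feature's differential-expression call in one omics layer."""

    feature_id: str
    layer: Literal["rna", "protein"]
    lfc: float
    p_value: float | None  # None = untestable
    p_adj: float | None
    significant: bool
    imputed_lfc: bool = False


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def pca_outliers(matrix: _LabeledMatrix, config: DEConfig = DEConfig()) -> list[str]:
    """Flag samples unusually far from their own group's centroid in PCA space.

    PCA is computed on log2(value + pseudocount) with features centered; the
    component sign is fixed so the largest-|loading| feature loads positively,
    making the scores (and hence the flag) deterministic.
    """
    for grp in ("case", "control"):
        n = len(matrix.samples_in(grp))
        if n < 3:
            raise ValueError(
                f"group {grp!r} has {n} samples; >=3 needed for a within-group "
                "distance spread"
            )
    X = np.log2(matrix.values.values.T + config.pseudocount)  # samples × features
    n_comp = min(config.pca_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    # sign convention: largest-|loading| feature positive per component
    for j in range(n_comp):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]

    samples = matrix.sample_ids
    out: list[str] = []
    for grp in ("case", "control"):
        idx = [i for i, s in enumerate(samples) if matrix.groups[s] == grp]
        pts = scores[idx]
        centroid = pts.mean(axis=0)
        dist = np.linalg.norm(pts - centroid, axis=1)
        thresh = dist.mean() + config.outlier_k_sd * dist.std(ddof=1)
        for i, d in zip(idx, dist):
            if d > thresh:
                out.append(samples[i])
    return out


# ---------------------------------------------------------------------------
# transcript DE
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over genes of count_gj / geometric-mean_g, where the
    median runs only over genes with strictly positive counts in every
    sample (the geometric mean is zero otherwise).
    """
    vals = counts.values.astype(float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has positive counts in every sample; cannot normalize")
    logv = np.log(vals[allpos])
    loggeo = logv.mean(axis=1)
    ratios = np.exp(logv - loggeo[:, None])
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-test p-values per row; NaN where both groups have
    zero variance (untestable)."""
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trip scipy's precision warning; they are flagged below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    var0 = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    p[var0] = np.nan
    return p


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    """Multiple-testing adjustment over the testable (finite) p-values."""
    p_adj = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        if method == "benjamini_hochberg":
            p_adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
        elif method == "bonferroni":
            p_adj[mask] = np.minimum(1.0, p[mask] * mask.sum())
        else:  # pragma: no cover
            raise ValueError(f"unknown adjustment {method!r}")
    return p_adj


def de_transcripts(counts: CountMatrix, config: DEConfig = DEConfig()) -> list[DERecord]:
    """Per-gene DE calls on a count matrix (see module docstring)."""
    for grp in ("case", "control"):
        if len(counts.samples_in(grp)) < 2:
            raise ValueError(f"group {grp!r} needs >=2 samples for transcript DE")
    if not counts.values.values.any():
        raise ValueError("all-zero count matrix")
    factors = size_factors(counts.values)
    norm = counts.values / factors
    case_cols = counts.samples_in("case")
    ctrl_cols = counts.samples_in("control")
    pc = config.pseudocount
    lfc = np.log2(
        (norm[case_cols].mean(axis=1) + pc) / (norm[ctrl_cols].mean(axis=1) + pc)
    ).values
    logn = np.log2(norm + pc)
    p = _welch(logn[case_cols].values, logn[ctrl_cols].values)
    p_adj = _adjust(p, config.rna_adjust)
    records = []
    for i, gene in enumerate(counts.feature_ids):
        testable = np.isfinite(p[i])
        sig = bool(
            testable and p_adj[i] < config.alpha and abs(lfc[i]) > config.lfc_min
        )
        records.append(
            DERecord(
                feature_id=gene,
                layer="rna",
                lfc=float(lfc[i]),
                p_value=float(p[i]) if testable else None,
                p_adj=float(p_adj[i]) if testable else None,
                significant=sig,
            )
        )
    return records


# ---------------------------------------------------------------------------
# protein DE
# ---------------------------------------------------------------------------


def de_proteins(
    intensities: IntensityMatrix, config: DEConfig = DEConfig()
) -> list[DERecord]:
    """Per-protein DE calls with the one-group-only imputation rule."""
    case_cols = intensities.samples_in("case")
    ctrl_cols = intensities.samples_in("control")
    if not case_cols or not ctrl_cols:
        raise ValueError("both groups must have >=1 sample")
    vals = intensities.values
    mc = vals[case_cols].mean(axis=1).values
    mx = vals[ctrl_cols].mean(axis=1).values
    pc = config.pseudocount

    both = (mc > 0) & (mx > 0)
    one_only = ((mc > 0) & (mx == 0)) | ((mc == 0) & (mx > 0))
    neither = ~(both | one_only)
    if neither.any():
        log.warning("excluding %d proteins undetected in both groups", int(neither.sum()))

    lfc = np.full(len(vals), np.nan)
    lfc[both] = np.log2(mc[both] / mx[both])

    can_test = len(case_cols) >= 2 and len(ctrl_cols) >= 2
    p = np.full(len(vals), np.nan)
    if can_test:
        logv = np.log2(vals + pc)
        p_all = _welch(logv[case_cols].values, logv[ctrl_cols].values)
        keep = both | one_only
        p[keep] = p_all[keep]
    p_adj = _adjust(p, config.protein_adjust)

    finite = np.abs(lfc[np.isfinite(lfc)])
    if one_only.any():
        if config.l_max_override is not None:
            l_max = config.l_max_override
        elif finite.size:
            l_max = float(finite.max())
        else:
            raise ValueError(
                "one-group-only proteins present but no finite LFC to derive "
                "L_max from; set l_max_override"
            )

    records = []
    for i, prot in enumerate(intensities.feature_ids):
        if neither[i]:
            continue
        testable = np.isfinite(p[i])
        if one_only[i]:
            this_lfc = l_max if mc[i] > 0 else -l_max
            sig = bool(testable and p_adj[i] < config.alpha)
            imputed = True
        else:
            this_lfc = float(lfc[i])
            sig = bool(
                testable and p_adj[i] < config.alpha and abs(this_lfc) > config.lfc_min
            )
            imputed = False
        records.append(
            DERecord(
                feature_id=prot,
                layer="protein",
                lfc=float(this_lfc),
                p_value=float(p[i]) if testable else None,
                p_adj=float(p_adj[i]) if testable else None,
                significant=sig,
                imputed_lfc=imputed,
            )
        )
    return records
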