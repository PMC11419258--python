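"""Readers and writers for every external format the pipeline touches.

All tabular exchange is plain TSV. Signature libraries are accepted either as
long-format TSV (``signature_id, perturbagen, library, gene, lfc`` — the
canonical, diffable exchange format) or as GCT v1.2 with a sidecar metadata
TSV mapping each GCT column to a perturbagen and library. GCTX/HDF5 is not
supported.

Two contracts matter throughout:

* a missing signature value is an *absent key*, never 0 — downstream scoring
  treats unmeasured and unchanged genes differently;
* readers never silently coerce — every rejected cell is reported with its
  row/column location.

Every output file carries a ``# revex-screen v<version> seed=<seed>`` comment
header so a run can be traced back to its parameters.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

VALID_GROUPS = ("case", "control")


class ParseError(ValueError):
    """A malformed input file; the message carries row/column context."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class _LabeledMatrix:
    """Feature × sample matrix with a case/control group for every sample."""

    values: pd.DataFrame  # features (rows) × samples (columns)
    groups: Mapping[str, str]  # sample id -> "case" | "control"

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ParseError(f"duplicate feature id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise ParseError(f"sample {missing[0]!r} has no group assignment")
        bad = {g for g in self.groups.values() if g not in VALID_GROUPS}
        if bad:
            raise ParseError(f"unknown group label(s) {sorted(bad)}; expected {VALID_GROUPS}")
        present = set(self.groups[s] for s in cols)
        if set(VALID_GROUPS) - present:
            raise ParseError(f"both groups must be non-empty, got only {sorted(present)}")
        if (self.values.values < 0).any():
            r, c = np.argwhere(self.values.values < 0)[0]
            raise ParseError(
                f"negative value at feature {idx[r]!r}, sample {cols[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def drop_samples(self, samples: Iterable[str]) -> "_LabeledMatrix":
        drop = set(samples)
        keep = [s for s in self.values.columns if s not in drop]
        groups = {s: self.groups[s] for s in keep}
        return type(self)(self.values[keep], groups)


class CountMatrix(_LabeledMatrix):
    """Gene × sample read counts (nonnegative integers)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values.values
        if not np.issubdtype(vals.dtype, np.integer):
            frac = vals != np.floor(vals)
            if frac.any():
                r, c = np.argwhere(frac)[0]
                raise ParseError(
                    f"non-integer count at gene {self.values.index[r]!r}, "
                    f"sample {self.values.columns[c]!r}"
                )
            self.values = self.values.astype(np.int64)


class IntensityMatrix(_LabeledMatrix):
    """Protein × sample intensities; 0 means not detected."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(float)


@dataclass
class Signature:
    """One perturbation experiment's partial gene → log2-fold-change map."""

    signature_id: str
    perturbagen: str
    library: str
    lfc: dict[str, float]

    def __post_init__(self) -> None:
        if not self.lfc:
            raise ValueError(f"signature {self.signature_id!r} has no genes")

    @property
    def n_genes(self) -> int:
        return len(self.lfc)


@dataclass
class SignatureSet:
    """A library of signatures plus per-library screening cutoffs."""

    signatures: list[Signature]
    library_cutoffs: dict[str, float]

    def __post_init__(self) -> None:
        ids = [s.signature_id for s in self.signatures]
        if len(set(ids)) != len(ids):
            raise ParseError("duplicate signature ids in set")
        for sig in self.signatures:
            if sig.library not in self.library_cutoffs:
                raise ParseError(
                    f"library {sig.library!r} (signature {sig.signature_id!r}) "
                    "has no cutoff entry"
                )
        for lib, cut in self.library_cutoffs.items():
            if not cut < 0:
                raise ParseError(f"cutoff for library {lib!r} must be negative, got {cut}")

    def __len__(self) -> int:
        return len(self.signatures)


@dataclass
class AnnotationTable:
    """Per-drug annotations: BBB permeation probability, prior disease-trial
    count, approved indication. BBB may be missing (NaN)."""

    rows: pd.DataFrame  # index: drug; columns: bbb, n_trials, indication

    def __post_init__(self) -> None:
        if self.rows.index.has_duplicates:
            dup = self.rows.index[self.rows.index.duplicated()][0]
            raise ParseError(f"duplicate drug id {dup!r} in annotations")
        bbb = self.rows["bbb"].astype(float)
        bad = bbb[(bbb < 0) | (bbb > 1)].dropna()
        if len(bad):
            raise ParseError(f"bbb out of [0,1] for drug {bad.index[0]!r}: {bad.iloc[0]}")
        nt = self.rows["n_trials"]
        if (nt < 0).any():
            raise ParseError("n_trials must be >= 0")
        self.rows = self.rows.assign(bbb=bbb, n_trials=nt.astype(int))

    def __contains__(self, drug: str) -> bool:
        return drug in self.rows.index

    def get(self, drug: str) -> pd.Series | None:
        return self.rows.loc[drug] if drug in self.rows.index else None


# ---------------------------------------------------------------------------
# header / float formatting helpers
# ---------------------------------------------------------------------------


def _header(seed: int | None) -> str:
    tag = f"# revex-screen v{__version__}"
    if seed is not None:
        tag += f" seed={seed}"
    return tag + "\n"


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def read_groups(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ParseError(f"{path}: groups file must have columns 'sample', 'group'")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample {dup!r} in groups file")
    return dict(zip(df["sample"], df["group"]))


def read_matrix(
    path: str | Path, kind: str, groups_path: str | Path
) -> CountMatrix | IntensityMatrix:
    """Read a feature × sample TSV (first column = feature id) plus its
    sample→group sidecar. ``kind`` is ``"counts"`` (strict integers) or
    ``"intensities"``."""
    if kind not in ("counts", "intensities"):
        raise ValueError(f"kind must be 'counts' or 'intensities', got {kind!r}")
    df = _read_tsv(path)
    first = df.columns[0]
    df = df.set_index(first)
    df.index = df.index.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at "
                f"feature {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().values)[0]
        raise ParseError(f"{path}: empty cell at feature {df.index[r]!r}, sample {df.columns[c]!r}")
    groups = read_groups(groups_path)
    unknown = set(groups) - set(df.columns)
    if unknown:
        raise ParseError(f"{groups_path}: unknown sample {sorted(unknown)[0]!r} in groups file")
    cls = CountMatrix if kind == "counts" else IntensityMatrix
    return cls(df, groups)


def write_matrix(
    matrix: _LabeledMatrix,
    path: str | Path,
    groups_path: str | Path,
    seed: int | None = None,
) -> None:
    path, groups_path = Path(path), Path(groups_path)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        cols = matrix.sample_ids
        fh.write("feature\t" + "\t".join(cols) + "\n")
        integral = np.issubdtype(matrix.values.values.dtype, np.integer)
        for gene, row in matrix.values.iterrows():
            if integral:
                cells = "\t".join(str(int(v)) for v in row.values)
            else:
                cells = "\t".join(_fmt(v) for v in row.values)
            fh.write(f"{gene}\t{cells}\n")
    with open(groups_path, "w") as fh:
        fh.write(_header(seed))
        fh.write("sample\tgroup\n")
        for s in matrix.sample_ids:
            fh.write(f"{s}\t{matrix.groups[s]}\n")


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

DEFAULT_CUTOFF = -0.2


def _resolve_cutoffs(
    libraries: set[str], cutoffs: Mapping[str, float] | None
) -> dict[str, float]:
    out = {lib: DEFAULT_CUTOFF for lib in libraries}
    if cutoffs:
        for lib, cut in cutoffs.items():
            out[lib] = float(cut)
    return out


def read_signatures(
    path: str | Path,
    cutoffs: Mapping[str, float] | None = None,
    sidecar: str | Path | None = None,
) -> SignatureSet:
    """Read a signature library from long TSV or GCT v1.2.

    GCT files (magic ``#1.2``) need a ``sidecar`` TSV with columns
    ``signature_id, perturbagen, library``. Cells that are empty or ``NA``
    are treated as missing (the gene is absent from that signature's map).
    ``cutoffs`` overrides the default per-library screening cutoff of −0.2.
    """
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().strip()
    if magic == "#1.2":
        return _read_gct(path, cutoffs, sidecar)
    if magic.startswith("#1."):
        raise ParseError(f"{path}: unsupported GCT version {magic!r}")
    df = _read_tsv(path, dtype={"gene": str})
    need = ["signature_id", "perturbagen", "library", "gene", "lfc"]
    if list(df.columns[: len(need)]) != need:
        raise ParseError(
            f"{path}: expected long-format columns {need} or a GCT '#1.2' magic line, "
            f"got columns {list(df.columns)}"
        )
    meta: dict[str, tuple[str, str]] = {}
    lfcs: dict[str, dict[str, float]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.signature_id
        if sid not in meta:
            meta[sid] = (row.perturbagen, row.library)
            lfcs[sid] = {}
        elif meta[sid] != (row.perturbagen, row.library):
            raise ParseError(f"{path}: inconsistent metadata for signature {sid!r} at line {i}")
        raw = row.lfc
        if pd.isna(raw) or str(raw).strip() in ("NA", ""):
            continue  # missing value: gene omitted from the signature's map
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric lfc {raw!r} at line {i} "
                f"(signature {row.signature_id!r}, gene {row.gene!r})"
            ) from None
        if row.gene in lfcs[sid]:
            raise ParseError(
                f"{path}: duplicate gene {row.gene!r} within signature {sid!r} at line {i}"
            )
        lfcs[sid][row.gene] = val
    sigs = [Signature(sid, *meta[sid], lfcs[sid]) for sid in meta]
    libraries = {lib for _, lib in meta.values()}
    return SignatureSet(sigs, _resolve_cutoffs(libraries, cutoffs))


def _read_gct(
    path: Path, cutoffs: Mapping[str, float] | None, sidecar: str | Path | None
) -> SignatureSet:
    if sidecar is None:
        raise ParseError(f"{path}: GCT input requires a sidecar metadata TSV")
    with open(path) as fh:
        fh.readline()  # #1.2
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ParseError(f"{path}: malformed GCT dimensions line")
        nrows, ncols = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    if body.shape[0] != nrows or body.shape[1] - 2 != ncols:
        raise ParseError(
            f"{path}: GCT dimensions line says {nrows}×{ncols}, body is "
            f"{body.shape[0]}×{body.shape[1] - 2}"
        )
    meta = _read_tsv(sidecar, dtype=str).set_index("signature_id")
    sigs: list[Signature] = []
    genes = body.iloc[:, 0].astype(str)
    for col in body.columns[2:]:
        if col not in meta.index:
            raise ParseError(f"{sidecar}: no metadata row for GCT column {col!r}")
        vals = pd.to_numeric(body[col], errors="coerce")
        lfc = {g: float(v) for g, v in zip(genes, vals) if not pd.isna(v)}
        sigs.append(
            Signature(col, meta.loc[col, "perturbagen"], meta.loc[col, "library"], lfc)
        )
    libraries = {s.library for s in sigs}
    return SignatureSet(sigs, _resolve_cutoffs(libraries, cutoffs))


def write_signatures(sigs: SignatureSet, path: str | Path, seed: int | None = None) -> None:
    """Write a SignatureSet as canonical long TSV (signatures in id order,
    genes in lexicographic order)."""
    if not sigs.signatures:
        raise ValueError("refusing to write an empty signature set")
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("signature_id\tperturbagen\tlibrary\tgene\tlfc\n")
        for sig in sorted(sigs.signatures, key=lambda s: s.signature_id):
            for gene in sorted(sig.lfc):
                fh.write(
                    f"{sig.signature_id}\t{sig.perturbagen}\t{sig.library}\t"
                    f"{gene}\t{_fmt(sig.lfc[gene])}\n"
                )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> AnnotationTable:
    df = _read_tsv(path)
    need = ["drug", "bbb", "n_trials", "indication"]
    if list(df.columns[: len(need)]) != need:
        raise ParseError(f"{path}: expected columns {need}, got {list(df.columns)}")
    df["bbb"] = pd.to_numeric(df["bbb"].replace("NA", np.nan), errors="coerce")
    return AnnotationTable(df.set_index("drug")[["bbb", "n_trials", "indication"]])


def write_annotations(table: AnnotationTable, path: str | Path, seed: int | None = None) -> None:
    if not len(table.rows):
        raise ValueError("refusing to write an empty annotation table")
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("drug\tbbb\tn_trials\tindication\n")
        for drug, row in table.rows.sort_index().iterrows():
            fh.write(f"{drug}\t{_fmt(row['bbb'])}\t{int(row['n_trials'])}\t{row['indication']}\n")


# ---------------------------------------------------------------------------
# pipeline artifacts (profile / DE records / concordances / scorecards /
# clusters / truth tables)
# ---------------------------------------------------------------------------


def write_profile(profile, path: str | Path, seed: int | None = None) -> None:
    """Disease profile TSV: ``gene<TAB>lfc``, ascending lfc."""
    if profile.n == 0:
        raise ValueError("refusing to write an empty profile")
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("gene\tlfc\n")
        for gene, lfc in profile.entries.items():
            fh.write(f"{gene}\t{_fmt(lfc)}\n")


def read_profile(path: str | Path):
    from .profile_builder import DiseaseProfile

    df = _read_tsv(path, dtype={"gene": str})
    if list(df.columns[:2]) != ["gene", "lfc"]:
        raise ParseError(f"{path}: expected columns ['gene', 'lfc']")
    return DiseaseProfile(dict(zip(df["gene"], df["lfc"].astype(float))))


def write_de_records(records, path: str | Path, seed: int | None = None) -> None:
    """DE record TSV, rows sorted by (layer, feature_id)."""
    if not records:
        raise ValueError("refusing to write an empty DE record list")
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("feature_id\tlayer\tlfc\tp_value\tp_adj\tsignificant\timputed_lfc\n")
        for r in sorted(records, key=lambda r: (r.layer, r.feature_id)):
            fh.write(
                f"{r.feature_id}\t{r.layer}\t{_fmt(r.lfc)}\t{_fmt(r.p_value)}\t"
                f"{_fmt(r.p_adj)}\t{int(r.significant)}\t{int(r.imputed_lfc)}\n"
            )


def read_de_records(path: str | Path):
    from .diffexpr import DERecord

    df = _read_tsv(path, dtype={"feature_id": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DERecord(
                feature_id=row.feature_id,
                layer=row.layer,
                lfc=float(row.lfc) if not pd.isna(row.lfc) else float("nan"),
                p_value=None if pd.isna(row.p_value) else float(row.p_value),
                p_adj=None if pd.isna(row.p_adj) else float(row.p_adj),
                significant=bool(row.significant),
                imputed_lfc=bool(row.imputed_lfc),
            )
        )
    return out


def write_concordances(results, path: str | Path, seed: int | None = None) -> None:
    """Concordance TSV sorted ascending by r (flagged rows last)."""
    if not results:
        raise ValueError("refusing to write an empty concordance list")
    key = lambda c: (c.r is None or math.isnan(c.r), c.r if c.r is not None else 0.0, c.signature_id)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("signature_id\tperturbagen\tlibrary\tr\tn_overlap\tpassed\n")
        for c in sorted(results, key=key):
            rtxt = "NA" if c.r is None or math.isnan(c.r) else _fmt(c.r)
            fh.write(
                f"{c.signature_id}\t{c.perturbagen}\t{c.library}\t{rtxt}\t"
                f"{c.n_overlap}\t{int(c.passed)}\n"
            )


def read_concordances(path: str | Path):
    from .reversal_screen import ConcordanceResult

    df = _read_tsv(path, dtype={"signature_id": str})
    out = []
    for row in df.itertuples(index=False):
        r = float("nan") if (isinstance(row.r, str) and row.r == "NA") or pd.isna(row.r) else float(row.r)
        out.append(
            ConcordanceResult(
                signature_id=row.signature_id,
                perturbagen=row.perturbagen,
                library=row.library,
                r=r,
                n_overlap=int(row.n_overlap),
                passed=bool(row.passed),
            )
        )
    return out


def write_scorecards(cards, path: str | Path, seed: int | None = None) -> None:
    """ScoreCard TSV sorted by rank (i.e. RS descending)."""
    if not cards:
        raise ValueError("refusing to write an empty scorecard list")
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("drug\trs\toc\tcluster\tin_reversal_cluster\trank\tpasses_filters\n")
        for c in sorted(cards, key=lambda c: c.rank):
            fh.write(
                f"{c.drug}\t{_fmt(c.rs)}\t{_fmt(c.oc)}\t{c.cluster}\t"
                f"{int(c.in_reversal_cluster)}\t{c.rank}\t{int(c.passes_filters)}\n"
            )


def read_scorecards(path: str | Path):
    from .prioritize import ScoreCard

    df = _read_tsv(path, dtype={"drug": str})
    return [
        ScoreCard(
            drug=r.drug,
            rs=float(r.rs),
            oc=float(r.oc),
            cluster=int(r.cluster),
            in_reversal_cluster=bool(r.in_reversal_cluster),
            rank=int(r.rank),
            passes_filters=bool(r.passes_filters),
        )
        for r in df.itertuples(index=False)
    ]


def write_clusters(assignments, path: str | Path, seed: int | None = None) -> None:
    """Cluster assignment TSV sorted by column id."""
    if not assignments:
        raise ValueError("refusing to write an empty cluster assignment list")
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("column_id\tcluster\tis_profile_column\n")
        for a in sorted(assignments, key=lambda a: a.column_id):
            fh.write(f"{a.column_id}\t{a.cluster}\t{int(a.is_profile_column)}\n")


def write_results(obj, path: str | Path, seed: int | None = None) -> None:
    """Dispatch writer: profile, DE records, concordances, scorecards or
    cluster assignments, by inspecting the object. Empty input is an error."""
    from .profile_builder import DiseaseProfile

    if isinstance(obj, DiseaseProfile):
        write_profile(obj, path, seed)
        return
    seq = list(obj)
    if not seq:
        raise ValueError("refusing to write an empty result")
    head = seq[0]
    if hasattr(head, "p_adj"):
        write_de_records(seq, path, seed)
    elif hasattr(head, "n_overlap"):
        write_concordances(seq, path, seed)
    elif hasattr(head, "rs"):
        write_scorecards(seq, path, seed)
    elif hasattr(head, "column_id"):
        write_clusters(seq, path, seed)
    else:
        raise TypeError(f"no writer for objects of type {type(head).__name__}")


def write_drug_profiles(profiles, path: str | Path, seed: int | None = None) -> None:
    """Drug-level aggregate TSV: ``drug, n_signatures, gene, lfc`` (long
    format, drugs then genes in lexicographic order)."""
    if not profiles:
        raise ValueError("refusing to write an empty drug-profile list")
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("drug\tn_signatures\tgene\tlfc\n")
        for dp in sorted(profiles, key=lambda d: d.drug):
            for gene in sorted(dp.lfc):
                fh.write(f"{dp.drug}\t{dp.n_signatures}\t{gene}\t{_fmt(dp.lfc[gene])}\n")


def read_drug_profiles(path: str | Path):
    from .reversal_screen import DrugProfile

    df = _read_tsv(path, dtype={"drug": str, "gene": str})
    out = []
    for drug, sub in df.groupby("drug", sort=True):
        out.append(
            DrugProfile(
                drug=str(drug),
                lfc=dict(zip(sub["gene"], sub["lfc"].astype(float))),
                n_signatures=int(sub["n_signatures"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# truth tables
# ---------------------------------------------------------------------------

TRUTH_MAGIC = "# truth_table v1"


def write_truth_table(truth, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(TRUTH_MAGIC + "\n")
        fh.write(_header(seed))
        fh.write("kind\tkey\tvalue\talpha\n")
        for gene in sorted(truth.de_genes):
            fh.write(f"de_gene\t{gene}\t{_fmt(truth.de_genes[gene])}\tNA\n")
        for drug in sorted(truth.drug_archetypes):
            label, alpha = truth.drug_archetypes[drug]
            fh.write(f"drug\t{drug}\t{label}\t{_fmt(alpha) if alpha is not None else 'NA'}\n")


def read_truth_table(path: str | Path):
    from .synthetic_data import TruthTable

    with open(path) as fh:
        if fh.readline().strip() != TRUTH_MAGIC:
            raise ParseError(f"{path}: missing '{TRUTH_MAGIC}' magic line")
    df = _read_tsv(path, dtype={"key": str})
    de = {}
    drugs = {}
    for row in df.itertuples(index=False):
        if row.kind == "de_gene":
            de[row.key] = float(row.value)
        elif row.kind == "drug":
            alpha = None if (pd.isna(row.alpha) or row.alpha == "NA") else float(row.alpha)
            drugs[row.key] = (row.value, alpha)
        else:
            raise ParseError(f"{path}: unknown truth row kind {row.kind!r}")
    return TruthTable(de_genes=de, drug_archetypes=drugs)
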