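"""Count-matrix, metadata and annotation containers with loading, validation,
normalization (CPM/FPKM) and expression filtering.

The pipeline starts from gene-level read-count matrices (features x samples):
a PWBC mRNA layer and a circulating-miRNA layer, plus a sample table giving
the pregnancy outcome group of each animal and its sampling year, and a
feature annotation giving biotype and transcript length.

Pipeline order is fixed: CPM is computed on the raw matrix using full library
sizes (column sums over *all* features present), then lowly expressed
features are removed (CPM >= min_cpm in >= min_samples samples), then the
matrix is subset to the biotype of interest. Library sizes are never
recomputed after subsetting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "Layer",
    "Outcome",
    "Unit",
    "CountMatrix",
    "SampleTable",
    "FeatureAnnotation",
    "ExpressionMatrix",
    "read_counts",
    "read_sample_table",
    "read_annotation",
    "compute_cpm",
    "compute_fpkm",
    "log2_cpm",
    "filter_expressed",
    "subset_biotype",
]


class Layer(str, Enum):
    MRNA = "mRNA"
    MIRNA = "miRNA"


class Outcome(str, Enum):
    """Pregnancy outcome after the breeding season."""

    AI_PREG = "AI_PREG"
    NB_PREG = "NB_PREG"
    NON_PREG = "NON_PREG"


class Unit(str, Enum):
    CPM = "CPM"
    LOG2_CPM = "LOG2_CPM"
    FPKM = "FPKM"


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, for one RNA layer."""

    counts: pd.DataFrame  # rows: feature_ids, cols: sample_ids, int64
    layer: Layer

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if df.shape[1] < 2:
            raise ValueError("a count matrix needs at least 2 samples")
        arr = df.to_numpy()
        if np.issubdtype(arr.dtype, np.floating):
            if not np.all(np.isfinite(arr)):
                raise ValueError("counts contain non-finite values")
            if np.any(arr != np.floor(arr)):
                bad = df.index[np.any(arr != np.floor(arr), axis=1)][:5].tolist()
                raise ValueError(f"non-integral counts for features {bad}")
            self.counts = df.astype(np.int64)
            arr = self.counts.to_numpy()
        if np.any(arr < 0):
            bad = df.index[np.any(arr < 0, axis=1)][:5].tolist()
            raise ValueError(f"negative counts for features {bad}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Column sums over all features present in this matrix."""
        return self.counts.sum(axis=0)

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feature_ids)], self.layer)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.layer)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.layer == other.layer
            and self.counts.equals(other.counts)
        )


@dataclass
class SampleTable:
    """Sample metadata: outcome group and cohort year per sample."""

    table: pd.DataFrame  # index: sample_id; columns: outcome, year

    def __post_init__(self) -> None:
        t = self.table
        if "outcome" not in t.columns:
            raise ValueError("sample table needs an 'outcome' column")
        if "year" not in t.columns:
            self.table = t = t.assign(year=1)
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample table")
        bad = set(t["outcome"]) - {o.value for o in Outcome}
        if bad:
            raise ValueError(f"unknown outcome labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def outcomes(self, sample_ids=None) -> pd.Series:
        t = self.table["outcome"]
        return t if sample_ids is None else t.loc[list(sample_ids)]

    def years(self, sample_ids=None) -> pd.Series:
        t = self.table["year"]
        return t if sample_ids is None else t.loc[list(sample_ids)]

    def group_samples(self, outcome: Outcome | str, year: int | None = None) -> list[str]:
        o = Outcome(outcome).value
        mask = self.table["outcome"] == o
        if year is not None:
            mask &= self.table["year"] == year
        return list(self.table.index[mask])

    def check_covers(self, cm: CountMatrix) -> None:
        missing = set(cm.sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")


@dataclass
class FeatureAnnotation:
    """Feature biotype, transcript length (bp) and optional symbol."""

    table: pd.DataFrame  # index: feature_id; columns: biotype, length_bp[, symbol]

    def __post_init__(self) -> None:
        t = self.table
        for col in ("biotype", "length_bp"):
            if col not in t.columns:
                raise ValueError(f"annotation needs a '{col}' column")
        if t.index.has_duplicates:
            raise ValueError("duplicate feature ids in annotation")
        if (t["length_bp"] <= 0).any():
            bad = t.index[t["length_bp"] <= 0][:5].tolist()
            raise ValueError(f"non-positive transcript lengths for {bad}")
        if t["biotype"].isna().any() or (t["biotype"].astype(str) == "").any():
            raise ValueError("empty biotype entries in annotation")

    def lengths(self, feature_ids) -> pd.Series:
        ids = list(feature_ids)
        missing = [f for f in ids if f not in self.table.index]
        if missing:
            raise KeyError(f"features without annotated length: {missing[:10]}")
        return self.table.loc[ids, "length_bp"]


@dataclass
class ExpressionMatrix:
    """Real-valued expression, features x samples, in a declared unit."""

    values: pd.DataFrame
    unit: Unit
    # library sizes used for normalization (full-matrix column sums)
    library_sizes: pd.Series | None = field(default=None)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.unit, self.library_sizes)


# ---------------------------------------------------------------------------
# readers


def read_counts(path: str | Path, layer: Layer | str) -> CountMatrix:
    """Read a count matrix from TSV (first column feature id, header row
    sample ids) or MatrixMarket ``.mtx`` with ``features.tsv`` /
    ``samples.tsv`` sidecars in the same directory.
    """
    path = Path(path)
    layer = Layer(layer)
    if path.suffix == ".mtx":
        mat = mmread(str(path))
        mat = np.asarray(mat.toarray() if hasattr(mat, "toarray") else mat)
        feats = pd.read_csv(path.parent / "features.tsv", sep="\t", header=None)[0].tolist()
        samps = pd.read_csv(path.parent / "samples.tsv", sep="\t", header=None)[0].tolist()
        if mat.shape != (len(feats), len(samps)):
            raise ValueError(
                f"mtx shape {mat.shape} does not match sidecars ({len(feats)} features, {len(samps)} samples)"
            )
        df = pd.DataFrame(mat, index=feats, columns=samps)
        return CountMatrix(df, layer)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse count TSV {path}: {exc}") from exc
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:3].tolist()
            raise ValueError(f"non-numeric count entries in column '{col}' (e.g. features {bad_rows})")
    return CountMatrix(df, layer)


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in df.columns:
        raise ValueError("metadata TSV needs a 'sample_id' column")
    return SampleTable(df.set_index("sample_id"))


def read_annotation(path: str | Path) -> FeatureAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "feature_id" not in df.columns:
        raise ValueError("annotation TSV needs a 'feature_id' column")
    return FeatureAnnotation(df.set_index("feature_id"))


# ---------------------------------------------------------------------------
# normalized units


def _library_sizes_checked(cm: CountMatrix) -> np.ndarray:
    lib = cm.library_sizes()
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValueError(f"zero library size for samples {zero}")
    return lib.to_numpy(dtype=float)


def compute_cpm(cm: CountMatrix) -> ExpressionMatrix:
    """Counts per million: count / library size * 1e6, per sample."""
    lib = _library_sizes_checked(cm)
    vals = cm.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    return ExpressionMatrix(
        pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns),
        Unit.CPM,
        cm.library_sizes(),
    )


def compute_fpkm(cm: CountMatrix, ann: FeatureAnnotation) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads."""
    lib = _library_sizes_checked(cm)
    lengths = ann.lengths(cm.feature_ids).to_numpy(dtype=float)
    vals = cm.counts.to_numpy(dtype=float) / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns),
        Unit.FPKM,
        cm.library_sizes(),
    )


def log2_cpm(cm: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount); the working scale for all correlations."""
    em = compute_cpm(cm)
    vals = np.log2(em.values.to_numpy() + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=em.values.index, columns=em.values.columns),
        Unit.LOG2_CPM,
        em.library_sizes,
    )


# ---------------------------------------------------------------------------
# filtering


def filter_expressed(
    em: ExpressionMatrix,
    cm: CountMatrix,
    min_cpm: float = 2.0,
    min_samples: int = 5,
) -> CountMatrix:
    """Keep features with CPM >= ``min_cpm`` in at least ``min_samples``
    samples (inclusive thresholds). Defaults match the mRNA layer; use
    ``min_cpm=1`` for the miRNA layer.
    """
    if em.unit is not Unit.CPM:
        raise ValueError("filter_expressed expects a CPM matrix")
    if min_samples > cm.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {cm.n_samples} available samples"
        )
    cpm = em.values.loc[cm.feature_ids, cm.sample_ids].to_numpy()
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    kept = [f for f, k in zip(cm.feature_ids, keep) if k]
    logger.info(
        "expression filter (CPM>=%s in >=%d samples): %d/%d features kept",
        min_cpm, min_samples, len(kept), cm.n_features,
    )
    return cm.subset_features(kept)


def subset_biotype(cm: CountMatrix, ann: FeatureAnnotation, biotype: str) -> CountMatrix:
    """Keep features annotated with the given biotype; unannotated features
    are dropped with a logged count. An empty result warns, not errors."""
    annotated = [f for f in cm.feature_ids if f in ann.table.index]
    n_unannot = cm.n_features - len(annotated)
    if n_unannot:
        logger.info("dropping %d features without annotation", n_unannot)
    keep = [f for f in annotated if ann.table.at[f, "biotype"] == biotype]
    if not keep:
        logger.warning("no features with biotype '%s' remain", biotype)
    logger.info("biotype '%s': %d/%d features kept", biotype, len(keep), cm.n_features)
    return CountMatrix(cm.counts.loc[keep], cm.layer)
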