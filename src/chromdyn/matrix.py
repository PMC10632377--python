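"""Peak × sample accessibility matrices: counting, normalization, partition.

The processing chain mirrors a bulk ATAC-seq time-course workflow: fragment
counts over a merged peak universe are converted to FPKM (fragments per
kilobase of peak per million fragments), quantile-normalized across samples,
split into "static" (coefficient of variation below threshold) and "dynamic"
peaks, and the dynamic peaks row z-scored for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .intervals import GenomicIntervalSet, build_trees

__all__ = [
    "SampleMatrix",
    "DynamicPartition",
    "read_sample_metadata",
    "count_fragments",
    "fpkm",
    "quantile_normalize",
    "cv_partition",
    "zscore_rows",
    "sample_pca",
]

#: Canonical condition ordering for the metastasis time course.
CONDITION_ORDER = ("invitro", "early", "late")


def order_conditions(conditions: Iterable[str]) -> list[str]:
    """Order condition labels: the canonical time course first, then others
    in first-appearance order."""
    seen: list[str] = []
    for c in conditions:
        if c not in seen:
            seen.append(c)
    known = [c for c in CONDITION_ORDER if c in seen]
    other = [c for c in seen if c not in CONDITION_ORDER]
    return known + other


@dataclass
class SampleMatrix:
    """A features × samples matrix with per-sample metadata.

    Parameters
    ----------
    values
        Nonnegative reals; index = peak (or gene) ids, columns = sample ids.
    samples
        Per-sample metadata indexed by sample id with columns ``condition``
        and ``replicate``; aligned to the value columns.
    totals
        Per-sample total fragment count used for FPKM scaling.  Defaults to
        the column sums of ``values``.
    lengths
        Per-peak length in bp (for FPKM); optional.
    nonnegative
        Enforce nonnegative entries (counts, FPKM, TPM).  Derived matrices
        such as row z-scores set this to False.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    totals: pd.Series | None = None
    lengths: pd.Series | None = None
    nonnegative: bool = True

    def __post_init__(self) -> None:
        # axis labels carry no information here; normalize for equality checks
        self.values.index.name = None
        self.values.columns.name = None
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        if self.nonnegative and (self.values.values < 0).any():
            raise ValueError("matrix entries must be nonnegative")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        self.samples = self.samples.loc[self.values.columns]
        if self.totals is None:
            self.totals = self.values.sum(axis=0).astype(float)
        else:
            self.totals = self.totals.loc[self.values.columns].astype(float)
        if (self.totals <= 0).any():
            raise ValueError("per-sample totals must be positive")
        if self.lengths is not None:
            self.lengths = self.lengths.loc[self.values.index]

    @property
    def peak_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> pd.Series:
        return self.samples["condition"]

    def condition_order(self) -> list[str]:
        return order_conditions(self.conditions)

    def condition_means(self) -> pd.DataFrame:
        """Mean value per feature per condition (columns in canonical order)."""
        means = self.values.T.groupby(self.conditions).mean().T
        return means[self.condition_order()]

    def with_values(self, values: pd.DataFrame, nonnegative: bool | None = None) -> "SampleMatrix":
        return SampleMatrix(
            values=values,
            samples=self.samples.copy(),
            totals=self.totals.copy(),
            lengths=None if self.lengths is None else self.lengths.copy(),
            nonnegative=self.nonnegative if nonnegative is None else nonnegative,
        )

    def subset_rows(self, ids: Iterable[str]) -> "SampleMatrix":
        ids = list(ids)
        return SampleMatrix(
            values=self.values.loc[ids],
            samples=self.samples.copy(),
            totals=self.totals.copy(),
            lengths=None if self.lengths is None else self.lengths.loc[ids],
            nonnegative=self.nonnegative,
        )

    # ---------------------------------------------------------------- I/O
    def write(self, counts_path: str | Path, metadata_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "peak_id"
        out.to_csv(counts_path, sep="\t")
        if metadata_path is not None:
            meta = self.samples.copy()
            meta["total_fragments"] = self.totals
            meta.index.name = "sample_id"
            meta.to_csv(metadata_path, sep="\t")

    @classmethod
    def read(
        cls,
        counts_path: str | Path,
        metadata_path: str | Path,
        lengths: pd.Series | None = None,
    ) -> "SampleMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        values.index = values.index.astype(str).rename(None)
        meta = read_sample_metadata(metadata_path)
        totals = meta.pop("total_fragments") if "total_fragments" in meta else None
        return cls(values=values, samples=meta, totals=totals, lengths=lengths)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    required = {"condition", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    return meta


@dataclass
class DynamicPartition:
    """Static/dynamic split of peaks by coefficient of variation."""

    dynamic_ids: list[str]
    static_ids: list[str]
    cv: pd.Series
    threshold: float

    def __post_init__(self) -> None:
        overlap = set(self.dynamic_ids) & set(self.static_ids)
        if overlap:
            raise ValueError("dynamic and static peak sets overlap")


def count_fragments(
    fragments: Mapping[str, GenomicIntervalSet],
    universe: GenomicIntervalSet,
    samples: pd.DataFrame,
) -> SampleMatrix:
    """Count, per sample, fragments overlapping each universe peak by ≥1 bp.

    A fragment contributes at most once to each peak it overlaps (but may hit
    several peaks).  Per-sample totals are the fragment counts, so that FPKM
    from this matrix is per million *fragments*, not per million in-peak hits.
    """
    trees = build_trees(universe)
    n_peaks = len(universe)
    sample_ids = list(fragments)
    counts = np.zeros((n_peaks, len(sample_ids)), dtype=np.int64)
    totals = {}
    for j, sid in enumerate(sample_ids):
        frags = fragments[sid]
        if universe.genome is not None and frags.genome is not None:
            if frags.genome != universe.genome:
                raise ValueError(f"sample {sid}: fragment genome differs from universe")
        totals[sid] = float(len(frags))
        for frag in frags:
            tree = trees.get(frag.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(frag.start, frag.end):
                counts[hit.data, j] += 1
    peak_ids = [
        iv.id if iv.id is not None else f"peak_{i}" for i, iv in enumerate(universe)
    ]
    values = pd.DataFrame(counts, index=peak_ids, columns=sample_ids)
    lengths = pd.Series([len(iv) for iv in universe], index=peak_ids, dtype=float)
    return SampleMatrix(
        values=values,
        samples=samples,
        totals=pd.Series(totals),
        lengths=lengths,
    )


def fpkm(counts: SampleMatrix) -> SampleMatrix:
    """Fragments per kilobase of peak per million total fragments.

    ``fpkm(i, j) = count(i, j) / ((length_i / 1e3) * (total_j / 1e6))``
    """
    if counts.lengths is None:
        raise ValueError("peak lengths are required for FPKM")
    if (counts.lengths <= 0).any():
        bad = counts.lengths.index[counts.lengths <= 0][0]
        raise ValueError(f"zero-length peak: {bad}")
    kb = counts.lengths.values[:, None] / 1e3
    per_million = counts.totals.values[None, :] / 1e6
    values = counts.values / (kb * per_million)
    out = counts.with_values(values)
    out.lengths = counts.lengths.copy()
    return out


def _quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization with the average-tie rule.

    The reference distribution is the row-mean of the column-sorted matrix;
    each value is replaced by the reference value at its within-column rank,
    and ties within a column receive the mean of the reference values over
    the ranks the tie group occupies.
    """
    x = df.values.astype(float)
    n, m = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    rows = np.arange(n)
    for j in range(m):
        col_sorted_vals = x[order[:, j], j]
        assigned = reference.copy()
        # average reference values over runs of tied input values
        start = 0
        for k in range(1, n + 1):
            if k == n or col_sorted_vals[k] != col_sorted_vals[start]:
                if k - start > 1:
                    assigned[start:k] = reference[start:k].mean()
                start = k
        out[order[:, j], j] = assigned
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(m: SampleMatrix) -> SampleMatrix:
    """Force every sample to share the mean sorted value distribution."""
    if m.values.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    out = m.with_values(_quantile_normalize_frame(m.values))
    out.lengths = None if m.lengths is None else m.lengths.copy()
    return out


def cv_partition(m: SampleMatrix, threshold: float = 0.10) -> DynamicPartition:
    """Split peaks into static (CV < threshold) and dynamic (CV ≥ threshold).

    CV is the sample standard deviation (ddof=1) over mean, pooled across all
    samples.  Rows with zero mean have undefined CV and are binned static.
    """
    if m.values.shape[1] < 2:
        raise ValueError("coefficient of variation requires at least 2 samples")
    mean = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    static_mask = (cv < threshold) | cv.isna()
    return DynamicPartition(
        dynamic_ids=list(m.values.index[~static_mask]),
        static_ids=list(m.values.index[static_mask]),
        cv=cv,
        threshold=threshold,
    )


def zscore_rows(m: SampleMatrix) -> SampleMatrix:
    """Row z-score: each row to mean 0, sample sd (ddof=1) 1."""
    mean = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=1)
    zero = sd.index[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance row cannot be z-scored: {zero[0]}")
    z = m.values.sub(mean, axis=0).div(sd, axis=0)
    return m.with_values(z, nonnegative=False)


def sample_pca(
    m: SampleMatrix,
    log_offset: float = 1.0,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over log2-transformed accessibility.

    Peaks are the variables (centered), samples the observations, matching a
    per-sample ordination of log2 normalized profiles.  Component signs are
    fixed by making the largest-magnitude peak loading positive, so results
    are deterministic.

    Returns
    -------
    coords : DataFrame samples × components ("PC1", ...)
    explained_variance : per-component variance (ddof=1 scale)
    """
    if m.values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = np.log2(m.values.values.T + log_offset)  # samples × peaks
    max_comp = min(x.shape[0] - 1, x.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    # deterministic sign convention
    for c in range(k):
        lead = np.argmax(np.abs(pca.components_[c]))
        if pca.components_[c, lead] < 0:
            pca.components_[c] *= -1
            coords[:, c] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=m.values.columns, columns=cols),
        pca.explained_variance_,
    )
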