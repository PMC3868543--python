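"""Count normalization, batch-effect removal, MDS diagnostics and
TF-based subtype clustering.

All steps operate on log2(count + 0.5), preserve the matrix shape and
append to a provenance trail. Within-sample covariate trends (GC, length)
are removed with a binned local-mean smoother; between-sample
normalization offers upper-quartile and full-quantile modes; batch removal
fits an additive least-squares model per gene and subtracts the batch
coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import (
    AnnotationError,
    ConfoundingError,
    DimensionError,
    InputError,
    NormalizationError,
)
from .matrix import CountMatrix

LOG_OFFSET = 0.5


@dataclass
class BatchFit:
    """Per-gene batch coefficients and their standard errors (treatment
    coding; the first batch level is the reference)."""

    reference: str
    coef: pd.DataFrame  # genes x non-reference batches
    se: pd.DataFrame


class NormalizedMatrix:
    """Log2-scale expression values plus provenance of applied steps."""

    def __init__(self, values: pd.DataFrame, gene_meta: pd.DataFrame,
                 sample_meta: pd.DataFrame, counts: pd.DataFrame | None = None,
                 provenance: list[dict] | None = None,
                 batch_fit: BatchFit | None = None):
        self.values = values
        self.gene_meta = gene_meta.loc[values.index]
        self.sample_meta = sample_meta.loc[values.columns]
        self.counts = counts
        self.provenance = list(provenance or [])
        self.batch_fit = batch_fit

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def _child(self, values: pd.DataFrame, step: dict,
               batch_fit: BatchFit | None = None) -> "NormalizedMatrix":
        return NormalizedMatrix(values, self.gene_meta, self.sample_meta,
                                counts=self.counts,
                                provenance=self.provenance + [step],
                                batch_fit=batch_fit or self.batch_fit)


def log_counts(cm: CountMatrix) -> NormalizedMatrix:
    """Entry point: log2(count + 0.5)."""
    values = np.log2(cm.counts.astype(float) + LOG_OFFSET)
    return NormalizedMatrix(values, cm.gene_meta, cm.sample_meta,
                            counts=cm.counts,
                            provenance=[{"step": "log2", "offset": LOG_OFFSET}])


def _as_normalized(data) -> NormalizedMatrix:
    if isinstance(data, CountMatrix):
        return log_counts(data)
    if isinstance(data, NormalizedMatrix):
        return data
    raise InputError(f"expected CountMatrix or NormalizedMatrix, got {type(data)}")


def _binned_trend(x: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """Local-mean smoother: quantile bins of x, bin-mean deviations from
    the column mean smoothed by a short moving average and shrunk toward
    zero where they are indistinguishable from sampling noise, linear
    interpolation between bin centers.

    The positive-part shrinkage keeps the step a near-no-op when no
    covariate trend exists while leaving genuine trends untouched.
    """
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(x, qs))
    if len(edges) < 3:
        return np.full_like(y, y.mean())
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    centers, means, ses = [], [], []
    grand = y.mean()
    for b in range(len(edges) - 1):
        mask = idx == b
        if mask.any():
            centers.append(x[mask].mean())
            means.append(y[mask].mean())
            ses.append(y[mask].std() / np.sqrt(mask.sum()))
    dev = np.asarray(means, dtype=float) - grand
    se = np.asarray(ses, dtype=float)
    if len(dev) >= 5:  # damp per-bin sampling noise
        kernel = np.full(5, 0.2)
        pad = lambda v: np.concatenate([v[2:0:-1], v, v[-2:-4:-1]])  # noqa: E731
        dev = np.convolve(pad(dev), kernel, mode="valid")
        se = np.sqrt(np.convolve(pad(se ** 2), kernel ** 2, mode="valid"))
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(np.abs(dev) > 0,
                          np.clip(1.0 - (3.0 * se / np.abs(dev)) ** 2, 0.0, 1.0),
                          0.0)
    return grand + np.interp(x, centers, dev * factor)


def within_sample_normalize(data, covariate: str = "gc",
                            n_bins: int = 20) -> NormalizedMatrix:
    """Remove, per sample, the smoothed trend of log2 expression on a gene
    covariate (``gc`` or ``length``), preserving each sample's mean."""
    nm = _as_normalized(data)
    if covariate not in ("gc", "length"):
        raise InputError(f"unsupported covariate {covariate!r}")
    if n_bins < 10:
        raise InputError("need at least 10 covariate bins")
    cov = nm.gene_meta[covariate].to_numpy(dtype=float)
    if covariate == "length":
        cov = np.log2(cov)
    if np.allclose(cov, cov[0]):
        warnings.warn(f"constant covariate {covariate!r}; nothing to normalize",
                      stacklevel=2)
        return nm._child(nm.values.copy(),
                         {"step": f"{covariate}_normalize", "applied": False})
    out = nm.values.copy()
    for col in out.columns:
        y = out[col].to_numpy(dtype=float)
        resid = y - _binned_trend(cov, y, n_bins)
        out[col] = resid - resid.mean() + y.mean()
    return nm._child(out, {"step": f"{covariate}_normalize", "n_bins": n_bins})


def between_sample_normalize(data, method: str = "upper_quartile") -> NormalizedMatrix:
    """Match sample distributions: ``upper_quartile`` shifts columns so the
    75th percentiles of expressed genes agree; ``full_quantile`` forces a
    common empirical distribution."""
    nm = _as_normalized(data)
    if nm.shape[1] < 2:
        raise NormalizationError("need at least 2 samples")
    vals = nm.values
    if nm.counts is not None and (nm.counts.sum(axis=0) == 0).any():
        raise NormalizationError("a sample has all-zero counts")
    if method == "upper_quartile":
        if nm.counts is not None:
            expressed = nm.counts > 0
        else:
            expressed = vals > np.log2(LOG_OFFSET)
        uq = pd.Series(
            {c: np.quantile(vals[c][expressed[c]], 0.75) for c in vals.columns})
        if uq.isna().any():
            raise NormalizationError("a sample has no expressed genes")
        out = vals - uq + uq.mean()
    elif method == "full_quantile":
        arr = vals.to_numpy(dtype=float)
        ref = np.sort(arr, axis=0).mean(axis=1)
        out_arr = np.empty_like(arr)
        order = np.argsort(arr, axis=0, kind="stable")
        for j in range(arr.shape[1]):
            out_arr[order[:, j], j] = ref
        out = pd.DataFrame(out_arr, index=vals.index, columns=vals.columns)
    else:
        raise InputError(f"unknown method {method!r}")
    return nm._child(out, {"step": "between_sample", "method": method})


def _dummies(labels: pd.Series) -> tuple[np.ndarray, list[str], str]:
    levels = list(dict.fromkeys(labels))
    ref = levels[0]
    cols = levels[1:]
    mat = np.column_stack([(labels == lv).to_numpy(dtype=float) for lv in cols]) \
        if cols else np.empty((len(labels), 0))
    return mat, cols, ref


def remove_batch_effect(data, batch: str | pd.Series = "center",
                        group: str | pd.Series = "subtype") -> NormalizedMatrix:
    """Fit, per gene, log2-expression ~ group + batch by least squares and
    subtract the batch component; biological group structure is preserved.

    ``batch`` / ``group`` may be sample-metadata column names or label
    series. Batches must not be perfectly confounded with groups and each
    batch needs >= 2 samples.
    """
    nm = _as_normalized(data)
    meta = nm.sample_meta

    def as_labels(spec) -> pd.Series:
        if isinstance(spec, str):
            if spec not in meta.columns:
                raise InputError(f"no sample-metadata column {spec!r}")
            return meta[spec].fillna("none").astype(str)
        return pd.Series(spec, index=meta.index).fillna("none").astype(str)

    batch_labels = as_labels(batch)
    group_labels = as_labels(group)
    if batch_labels.value_counts().min() < 2:
        raise InputError("every batch needs at least 2 samples")
    if batch_labels.nunique() < 2:
        warnings.warn("single batch; nothing to remove", stacklevel=2)
        return nm._child(nm.values.copy(), {"step": "batch_removal", "applied": False})

    g_mat, g_cols, _ = _dummies(group_labels)
    b_mat, b_cols, b_ref = _dummies(batch_labels)
    n = nm.shape[1]
    design = np.column_stack([np.ones(n), g_mat, b_mat])
    rank_full = np.linalg.matrix_rank(design)
    if rank_full < design.shape[1]:
        rank_wo_batch = np.linalg.matrix_rank(np.column_stack([np.ones(n), g_mat]))
        if rank_full == rank_wo_batch:
            raise ConfoundingError("batch perfectly confounded with group labels")
        raise InputError("rank-deficient design")

    y = nm.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    dof = n - design.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / max(dof, 1)
    xtx_inv = np.linalg.inv(design.T @ design)
    b_slice = slice(1 + len(g_cols), 1 + len(g_cols) + len(b_cols))
    coef = beta[b_slice, :].T  # genes x batches
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)[b_slice]))
    corrected = y - b_mat @ beta[b_slice, :]
    out = pd.DataFrame(corrected.T, index=nm.values.index, columns=nm.values.columns)
    fit = BatchFit(
        reference=b_ref,
        coef=pd.DataFrame(coef, index=nm.values.index, columns=b_cols),
        se=pd.DataFrame(se, index=nm.values.index, columns=b_cols),
    )
    return nm._child(out, {"step": "batch_removal", "batches": [b_ref] + b_cols},
                     batch_fit=fit)


def top_variable_genes(values: pd.DataFrame, n_top: int = 500) -> pd.DataFrame:
    variances = values.var(axis=1)
    keep = variances.sort_values(ascending=False).index[:n_top]
    return values.loc[keep]


def mds_embedding(data, k: int = 2, n_top: int = 500) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on Euclidean distances over the
    most variable genes. Deterministic up to axis sign; signs are fixed so
    each axis' largest-magnitude coordinate is positive."""
    nm = _as_normalized(data) if not isinstance(data, pd.DataFrame) else None
    values = nm.values if nm is not None else data
    n = values.shape[1]
    if n < 3:
        raise InputError("need at least 3 samples")
    if k >= n:
        raise DimensionError(f"k={k} must be < n_samples={n}")
    sub = top_variable_genes(values, n_top)
    d = squareform(pdist(sub.to_numpy(dtype=float).T))
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[order], 0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    for axis in range(k):
        i_max = np.argmax(np.abs(coords[:, axis]))
        if coords[i_max, axis] < 0:
            coords[:, axis] *= -1
    return pd.DataFrame(coords, index=values.columns,
                        columns=[f"MDS{i + 1}" for i in range(k)])


def cluster_subtypes(data, tf_list: tuple[str, ...] | list[str] = (
        "TAL1", "TLX1", "TLX3", "NKX2-5", "LYL1", "LMO2"),
        k: int = 6) -> pd.Series:
    """Hierarchical clustering (Ward linkage, Euclidean) of samples on the
    z-scored expression of the subtype-defining transcription factors."""
    nm = _as_normalized(data)
    missing = [tf for tf in tf_list if tf not in nm.values.index]
    if missing:
        raise AnnotationError(f"TF genes absent from matrix: {missing}")
    if k < 1:
        raise InputError("k must be >= 1")
    block = nm.values.loc[list(tf_list)]
    sd = block.std(axis=1).replace(0, 1.0)
    z = block.sub(block.mean(axis=1), axis=0).div(sd, axis=0)
    x = z.to_numpy(dtype=float).T  # samples x TFs
    if k == 1 or x.shape[0] == 1:
        labels = np.ones(x.shape[0], dtype=int)
    else:
        lk = linkage(x, method="ward")
        labels = fcluster(lk, t=k, criterion="maxclust")
    return pd.Series(labels, index=nm.values.columns, name="cluster")


def normalize_pipeline(cm: CountMatrix, steps: tuple[str, ...] = (
        "gc", "length", "uq", "batch")) -> NormalizedMatrix:
    """Apply the standard step order: within-sample (GC, length),
    between-sample, batch removal."""
    nm = log_counts(cm)
    for step in steps:
        if step == "gc":
            nm = within_sample_normalize(nm, "gc")
        elif step == "length":
            nm = within_sample_normalize(nm, "length")
        elif step == "uq":
            nm = between_sample_normalize(nm, "upper_quartile")
        elif step == "fq":
            nm = between_sample_normalize(nm, "full_quantile")
        elif step == "batch":
            group = "subtype" if nm.sample_meta["subtype"].notna().any() \
                else "sample_type"
            nm = remove_batch_effect(nm, batch="center", group=group)
        else:
            raise InputError(f"unknown normalization step {step!r}")
    return nm
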