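"""Signature discovery and projection: weighted clustering, APS, turnover.

The aneuploidy-associated protein signature (APS) is found by clustering
gene rows of the protein matrix with a Pearson-correlation distance in
which each strain's duplicated-chromosome measurements carry zero weight —
otherwise the trivial "own chromosome up twofold" signal dominates the
dendrogram. The signature is the set of proteins consistently up in every
strain; its per-strain intensity (mean log2 ratio over signature genes)
scales with the size of the duplicated chromosome.

Also here: projections of fixed gene sets (ESR up/down, APS) onto strains,
the up/down/unchanged binning used to compare matched strain pairs (e.g.
disome vs disome-ubp6Δ), and per-gene turnover slopes over short
degradation-inhibition timecourses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io_tables import GeneAnnotation, QuantMatrix


@dataclass
class WeightTable:
    """Per-(gene, strain) weights in [0, 1], same shape as the data matrix."""

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if np.nanmin(w) < 0 or np.nanmax(w) > 1:
            raise ValueError("weights must lie in [0, 1]")

    @classmethod
    def uniform(cls, matrix: QuantMatrix) -> "WeightTable":
        return cls(pd.DataFrame(1.0, index=matrix.data.index, columns=matrix.data.columns))

    @classmethod
    def downweight_duplicated(
        cls,
        matrix: QuantMatrix,
        annotation: GeneAnnotation,
        duplicated: Mapping[str, str | None] | None = None,
    ) -> "WeightTable":
        """Weight 0 for each strain's duplicated-chromosome genes, 1 elsewhere."""
        if duplicated is None:
            duplicated = matrix.duplicated_chromosomes()
        w = pd.DataFrame(1.0, index=matrix.data.index, columns=matrix.data.columns)
        for strain in matrix.strains:
            chrom = duplicated.get(strain)
            if chrom is None:
                continue
            on_dup = [g for g in annotation.genes_on(chrom) if g in w.index]
            w.loc[on_dup, strain] = 0.0
        return cls(w)


@dataclass
class SignatureSet:
    """A named gene set with its per-strain mean log2 ratio (intensity)."""

    name: str
    genes: list[str]
    intensity: pd.Series  # per strain
    sem: pd.Series  # per strain

    def __post_init__(self) -> None:
        self.genes = list(self.genes)


def weighted_pearson(
    x: Sequence[float], y: Sequence[float], w: Sequence[float]
) -> float:
    """Pearson correlation with observation weights.

    Means and (co)variances are weighted; with all weights equal this is the
    ordinary Pearson r, and with binary weights it equals Pearson r on the
    retained subset exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (w > 0)
    x, y, w = x[ok], y[ok], w[ok]
    if w.sum() <= 0 or ok.sum() < 3:
        raise ValueError("need >= 3 effective (positive-weight, finite) points")
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance")
    return float(cov / np.sqrt(vx * vy))


def _weighted_corr_matrix(X: np.ndarray, W: np.ndarray, block: int = 64) -> np.ndarray:
    """Pairwise weighted Pearson over rows; pair weight = w_i * w_j per column."""
    n = X.shape[0]
    R = np.empty((n, n))
    Xz = np.where(W > 0, X, 0.0)
    for start in range(0, n, block):
        stop = min(start + block, n)
        Wb = W[start:stop][:, None, :] * W[None, :, :]  # (b, n, m)
        sw = Wb.sum(axis=2)
        sw[sw == 0] = np.nan
        xb = Xz[start:stop][:, None, :]
        yb = Xz[None, :, :]
        mx = (Wb * xb).sum(axis=2) / sw
        my = (Wb * yb).sum(axis=2) / sw
        dx = xb - mx[:, :, None]
        dy = yb - my[:, :, None]
        cov = (Wb * dx * dy).sum(axis=2) / sw
        vx = (Wb * dx * dx).sum(axis=2) / sw
        vy = (Wb * dy * dy).sum(axis=2) / sw
        denom = np.sqrt(vx * vy)
        with np.errstate(invalid="ignore", divide="ignore"):
            R[start:stop] = cov / denom
    return R


def weighted_hcluster(
    matrix: QuantMatrix,
    weights: WeightTable | None = None,
    linkage: str = "average",
    min_observations: int = 3,
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of genes with distance 1 - weighted Pearson.

    Rows with fewer than ``min_observations`` positively weighted finite
    measurements are dropped (reported via warning). Pairs with undefined
    correlation (zero variance or no shared weight) get distance 1
    (uncorrelated). Returns (scipy linkage matrix, retained gene order).
    """
    if weights is None:
        weights = WeightTable.uniform(matrix)
    X = matrix.data.to_numpy(dtype=float)
    W = weights.weights.reindex(
        index=matrix.data.index, columns=matrix.data.columns
    ).to_numpy(dtype=float)
    W = np.where(np.isfinite(X), W, 0.0)
    keep = (W > 0).sum(axis=1) >= min_observations
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} gene rows with < "
                      f"{min_observations} weighted observations")
    genes = [g for g, k in zip(matrix.data.index, keep) if k]
    if len(genes) < 2:
        raise ValueError("need >= 2 retained gene rows to cluster")
    R = _weighted_corr_matrix(np.nan_to_num(X[keep]), W[keep])
    D = 1.0 - R
    D[~np.isfinite(D)] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, 2.0)
    condensed = D[np.triu_indices_from(D, k=1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    return Z, genes


def signature_projection(
    matrix: QuantMatrix, gene_set: Sequence[str], name: str = "signature"
) -> SignatureSet:
    """Per-strain mean and SEM of a fixed gene set (missing cells excluded)."""
    present = [g for g in gene_set if g in matrix.data.index]
    if not present:
        raise ValueError("gene set shares no genes with the matrix")
    block = matrix.data.loc[present]
    mean = block.mean(axis=0, skipna=True)
    n = block.notna().sum(axis=0)
    sem = block.std(axis=0, ddof=1, skipna=True) / np.sqrt(n.clip(lower=1))
    return SignatureSet(name=name, genes=present, intensity=mean, sem=sem)


def extract_consistent_up_signature(
    matrix: QuantMatrix,
    weights: WeightTable | None = None,
    min_log2: float = 0.0,
    mean_floor: float = 0.2,
    min_strains: int | None = None,
    method: str = "threshold",
    linkage: str = "average",
    min_cluster_size: int = 10,
    name: str = "APS",
) -> SignatureSet:
    """Genes consistently upregulated across strains, after down-weighting.

    method="threshold": a gene qualifies when its weighted (weight > 0)
    measurements exceed ``min_log2`` in at least ``min_strains`` strains
    (default: all its weighted strains) and its weighted mean is >=
    ``mean_floor``.

    method="cluster": build the weighted dendrogram and pick the cluster
    (any internal node of size >= ``min_cluster_size``) maximizing the
    minimum per-strain weighted mean.

    Both are documented approximations to a visual cluster selection; they
    agree on well-separated planted signatures.
    """
    if weights is None:
        weights = WeightTable.uniform(matrix)
    W = weights.weights.reindex(
        index=matrix.data.index, columns=matrix.data.columns
    ).to_numpy(dtype=float)
    X = matrix.data.to_numpy(dtype=float)
    W = np.where(np.isfinite(X), W, 0.0)
    Xz = np.nan_to_num(X)

    if method == "threshold":
        n_weighted = (W > 0).sum(axis=1)
        n_up = ((Xz > min_log2) & (W > 0)).sum(axis=1)
        need = n_weighted if min_strains is None else np.minimum(min_strains, n_weighted)
        with np.errstate(invalid="ignore"):
            wmean = (W * Xz).sum(axis=1) / W.sum(axis=1)
        qualifies = (n_weighted > 0) & (n_up >= need) & (wmean >= mean_floor)
        genes = [g for g, q in zip(matrix.data.index, qualifies) if q]
    elif method == "cluster":
        Z, retained = weighted_hcluster(matrix, weights, linkage=linkage)
        idx = {g: i for i, g in enumerate(retained)}
        sub_W = W[[matrix.data.index.get_loc(g) for g in retained]]
        sub_X = Xz[[matrix.data.index.get_loc(g) for g in retained]]
        root, nodes = hierarchy.to_tree(Z, rd=True)
        best_score, best_leaves = -np.inf, None
        for node in nodes:
            if node.get_count() < min_cluster_size:
                continue
            leaves = node.pre_order(lambda leaf: leaf.id)
            w = sub_W[leaves]
            x = sub_X[leaves]
            sw = w.sum(axis=0)
            with np.errstate(invalid="ignore"):
                strain_means = np.where(sw > 0, (w * x).sum(axis=0) / np.where(sw > 0, sw, 1), np.nan)
            score = np.nanmin(strain_means)
            if score > best_score:
                best_score, best_leaves = score, leaves
        if best_leaves is None:
            genes = []
        else:
            genes = [retained[i] for i in best_leaves]
        del idx
    else:
        raise ValueError(f"unknown method {method!r}")

    if not genes:
        warnings.warn("no genes qualify for the signature; returning empty set")
        empty = pd.Series(np.nan, index=matrix.data.columns)
        return SignatureSet(name=name, genes=[], intensity=empty, sem=empty)
    return signature_projection(matrix, genes, name=name)


def intensity_size_correlation(
    signature: SignatureSet, chromosome_sizes: Mapping[str, float]
) -> dict:
    """Pearson r and linear fit of signature intensity vs chromosome size.

    ``chromosome_sizes`` maps each strain to the size of its duplicated
    chromosome (bp when available, else gene count).
    """
    strains = [s for s in signature.intensity.index if s in chromosome_sizes]
    if len(strains) < 3:
        raise ValueError("need >= 3 strains with known chromosome sizes")
    x = np.array([chromosome_sizes[s] for s in strains], dtype=float)
    y = signature.intensity[strains].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    return {
        "r": float(fit.rvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p_value": float(fit.pvalue),
        "n": len(strains),
    }


def bin_and_compare(
    matrix_a: QuantMatrix,
    matrix_b: QuantMatrix,
    bounds: tuple[float, float] = (-0.4, 0.4),
) -> pd.DataFrame:
    """Bin genes on matrix_a (down/unchanged/up) and compare to matrix_b.

    Bins per strain: up (a >= upper bound), down (a <= lower bound),
    unchanged (between, exclusive). For every strain and bin the paired t
    test compares the matched per-gene values of the two matrices. Empty
    bins are reported with NaN statistics and no test.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lower < upper")
    shared_genes = matrix_a.data.index.intersection(matrix_b.data.index)
    shared_strains = [s for s in matrix_a.strains if s in set(matrix_b.strains)]
    if len(shared_genes) == 0 or not shared_strains:
        raise ValueError("matrices share no genes or no strains")
    rows = []
    for strain in shared_strains:
        a = matrix_a.data.loc[shared_genes, strain]
        b = matrix_b.data.loc[shared_genes, strain]
        ok = a.notna() & b.notna()
        a, b = a[ok], b[ok]
        bins = {
            "down": a <= lo,
            "unchanged": (a > lo) & (a < hi),
            "up": a >= hi,
        }
        for bin_name, mask in bins.items():
            av, bv = a[mask], b[mask]
            if av.empty:
                rows.append((strain, bin_name, 0, np.nan, np.nan, np.nan))
                continue
            diffs = bv - av
            if np.allclose(diffs, 0.0):
                p = 1.0  # identical pairs: no change, t = 0
            elif len(av) < 2:
                p = np.nan
            else:
                p = float(stats.ttest_rel(av, bv).pvalue)
            rows.append((strain, bin_name, int(len(av)), float(av.mean()),
                         float(bv.mean()), p))
    return pd.DataFrame(
        rows, columns=["strain", "bin", "n", "mean_a", "mean_b", "paired_t_p"]
    )


def fit_turnover_slope(
    timecourse: QuantMatrix, timepoints: Sequence[float] = (0.0, 90.0, 300.0)
) -> pd.Series:
    """Per-gene least-squares slope of log2 ratio vs time (log2 per second)."""
    t = np.asarray(timepoints, dtype=float)
    if len(t) != len(timecourse.strains):
        raise ValueError("one timepoint per matrix column required")
    if len(t) < 2:
        raise ValueError("need >= 2 timepoints")
    Y = timecourse.data.to_numpy(dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    # rows with missing cells fall back to pairwise-complete least squares
    full = np.isfinite(Y).all(axis=1)
    slopes = np.full(Y.shape[0], np.nan)
    Yf = Y[full]
    slopes[full] = (Yf - Yf.mean(axis=1, keepdims=True)) @ tc / denom
    for i in np.flatnonzero(~full):
        ok = np.isfinite(Y[i])
        if ok.sum() < 2:
            continue
        ti, yi = t[ok], Y[i, ok]
        tci = ti - ti.mean()
        slopes[i] = float(tci @ (yi - yi.mean()) / (tci @ tci))
    return pd.Series(slopes, index=timecourse.data.index, name="slope")


def turnover_chromosome_means(
    slopes: pd.Series, annotation: GeneAnnotation
) -> pd.Series:
    """Mean turnover slope per chromosome (missing slopes ignored)."""
    chrom = annotation.table["chromosome"].reindex(slopes.index)
    return slopes.groupby(chrom).mean()


def turnover_group_contrast(
    slopes: pd.Series, attenuated: set[str], duplicated_genes: set[str]
) -> dict:
    """Welch t test of slopes: attenuated vs not-attenuated duplicated genes."""
    dup = slopes[slopes.index.isin(duplicated_genes)].dropna()
    att = dup[dup.index.isin(attenuated)]
    not_att = dup[~dup.index.isin(attenuated)]
    if att.empty or not_att.empty:
        raise ValueError("both groups must be non-empty")
    t, p = stats.ttest_ind(att, not_att, equal_var=False)
    return {
        "mean_attenuated": float(att.mean()),
        "mean_not_attenuated": float(not_att.mean()),
        "n_attenuated": int(att.size),
        "n_not_attenuated": int(not_att.size),
        "t": float(t),
        "welch_p": float(p),
    }
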