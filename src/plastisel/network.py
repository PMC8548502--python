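"""Signed-gene-significance weighted co-expression network analysis.

The screen follows the WGCNA recipe: soft-thresholded unsigned adjacency
``a_ij = |cor(x_i, x_j)|**beta``, topological overlap

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

(the sum runs over u != i, j and k_i = sum_{u != i} a_iu), average-linkage
clustering of 1-TOM with a fixed-height dynamic tree cut, eigengene
merging at a squared-correlation threshold, and a signed gene-significance
score per gene: the Pearson correlation of its normalized expression with
the heat-tolerance phenotype (CT_MAX). Candidates are selected at
Benjamini-Hochberg FDR < alpha applied within each module, and their
regulator class (positive/negative) is the sign of the score.

Module labels are integers with 0 meaning "unassigned"; nonzero labels
are ordered by decreasing module size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, ValidationError
from .stats import bh_adjust, welch_t_test

log = logging.getLogger(__name__)

__all__ = [
    "NetworkResult",
    "choose_soft_power",
    "build_adjacency_tom",
    "detect_modules",
    "compute_eigengenes_and_merge",
    "gene_significance",
    "select_candidates",
    "validate_gs_subsets",
    "scale_free_fit",
]

# Guard against accidentally materializing a dense gene-gene matrix that
# does not fit desk-scale memory; override only deliberately.
MAX_GENES_DEFAULT = 20_000


@dataclass
class NetworkResult:
    """Co-expression network with module structure."""

    beta: int
    adjacency: np.ndarray | None
    tom: np.ndarray | None
    module_labels: pd.Series | None = None
    eigengenes: pd.DataFrame | None = None  # modules x samples
    merge_history: list = field(default_factory=list)


def _gene_correlation(norm: pd.DataFrame) -> np.ndarray:
    x = norm.to_numpy(dtype=float)
    sd = x.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(
            f"constant-expression gene(s) must be filtered upstream, "
            f"e.g. {list(norm.index[zero[:5]])}"
        )
    return np.corrcoef(x)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10(frequency) ~ log10(mean connectivity) regression
    over equal-width connectivity bins (the scale-free topology fit)."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    means = np.array([k[idx == b].mean() if freq[b] else np.nan
                      for b in range(n_bins)])
    ok = (freq > 0) & (means > 0)
    if ok.sum() < 3:
        return 0.0
    lx, ly = np.log10(means[ok]), np.log10(freq[ok] / freq.sum())
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        return 0.0
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r * r)


def choose_soft_power(norm: pd.DataFrame, candidate_powers=range(1, 21),
                      target_fit: float = 0.8, n_bins: int = 10) -> int:
    """Smallest soft-threshold power whose scale-free fit reaches
    ``target_fit``; if none does, the power maximizing the fit (warned)."""
    if norm.shape[0] < 3:
        raise ValidationError("need at least 3 genes to choose a power")
    cor = np.abs(_gene_correlation(norm))
    powers = list(candidate_powers)
    fits = []
    for beta in powers:
        adj = cor ** beta
        k = adj.sum(axis=0) - 1.0
        fits.append(scale_free_fit(k, n_bins=n_bins))
    fits = np.asarray(fits)
    reaching = np.flatnonzero(fits >= target_fit)
    if reaching.size:
        return int(powers[reaching[0]])
    best = int(np.argmax(fits))
    log.warning("no candidate power reaches fit %.2f; best fit %.3f at beta=%d",
                target_fit, fits[best], powers[best])
    return int(powers[best])


def build_adjacency_tom(norm: pd.DataFrame, beta: int,
                        max_genes: int = MAX_GENES_DEFAULT) -> NetworkResult:
    """Unsigned soft-threshold adjacency and topological overlap matrix."""
    if beta < 1:
        raise ConfigurationError("beta must be >= 1")
    n = norm.shape[0]
    if n > max_genes:
        raise ConfigurationError(
            f"{n} genes exceeds the {max_genes}-gene memory guard; "
            "pass a larger max_genes to override")
    cor = _gene_correlation(norm)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    tom = tom_similarity(adj)
    return NetworkResult(beta=int(beta), adjacency=adj, tom=tom)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap from an adjacency matrix with unit diagonal."""
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=0) - 1.0  # connectivity excludes self
    # (A@A)_ij counts u=i and u=j (each contributes a_ij with unit diagonal);
    # drop both, then add back the direct edge a_ij. In-place to keep the
    # peak at two n x n temporaries.
    tom = a @ a
    tom -= a
    denom = np.minimum.outer(k, k)
    denom += 1.0
    denom -= a
    bad = denom <= 0
    denom[bad] = 1.0
    tom /= denom
    tom[bad] = 1.0
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    return tom


def detect_modules(tom: np.ndarray, min_module_size: int = 30,
                   cut_height: float = 0.99) -> np.ndarray:
    """Fixed-height dynamic tree cut on average-linkage clustering of
    1-TOM; branches below ``min_module_size`` get label 0; surviving
    modules are labeled 1..K by decreasing size."""
    if min_module_size < 2:
        raise ConfigurationError("min_module_size must be >= 2")
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    # numerical asymmetry from the matrix products breaks squareform
    diss = (diss + diss.T) / 2.0
    z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    return _relabel_by_size(raw, min_module_size)


def _relabel_by_size(raw_labels: np.ndarray, min_size: int) -> np.ndarray:
    """Relabel nonzero cluster ids as 1..K by decreasing size; ids with
    fewer than ``min_size`` members (and id 0) become 0."""
    labels = np.zeros_like(raw_labels, dtype=int)
    ids, counts = np.unique(raw_labels, return_counts=True)
    nonzero = ids != 0
    ids, counts = ids[nonzero], counts[nonzero]
    keep = ids[counts >= min_size]
    sizes = counts[counts >= min_size]
    # order by descending size, ties broken by first-seen id for determinism
    order = np.lexsort((keep, -sizes))
    for new, pos in enumerate(order, start=1):
        labels[raw_labels == keep[pos]] = new
    return labels


def _eigengene(block: np.ndarray) -> np.ndarray:
    """First principal component across samples of row-standardized
    expression, unit norm, sign-oriented to the mean profile."""
    x = block - block.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x / sd
    if x.shape[0] == 1:
        v = x[0]
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else v
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    v = vt[0]
    if np.dot(v, x.mean(axis=0)) < 0:
        v = -v
    return v


def compute_eigengenes_and_merge(norm: pd.DataFrame, labels: np.ndarray,
                                 merge_r2: float = 0.75,
                                 beta: int | None = None) -> NetworkResult:
    """Module eigengenes plus iterative merging of module pairs whose
    eigengene correlation satisfies r^2 >= merge_r2 (most correlated pair
    first), recomputing eigengenes after each merge."""
    labels = np.asarray(labels, dtype=int).copy()
    if not (labels > 0).any():
        raise ValidationError("no non-zero modules to summarize")
    x = norm.to_numpy(dtype=float)
    history: list[tuple[int, int, float]] = []

    def eigengene_table(labs):
        mods = sorted(set(labs[labs > 0]))
        return mods, {m: _eigengene(x[labs == m]) for m in mods}

    while True:
        mods, eig = eigengene_table(labels)
        if len(mods) < 2:
            break
        best = None
        for i, mi in enumerate(mods):
            for mj in mods[i + 1:]:
                r = float(np.corrcoef(eig[mi], eig[mj])[0, 1])
                if r * r >= merge_r2 and (best is None or r * r > best[2] ** 2):
                    best = (mi, mj, r)
        if best is None:
            break
        mi, mj, r = best
        history.append((mi, mj, r))
        labels[labels == mj] = mi
    # compact surviving labels, ordered by descending module size
    labels = _relabel_by_size(labels, 1)
    mods, eig = eigengene_table(labels)
    eigengenes = pd.DataFrame(
        {m: eig[m] for m in mods}, index=norm.columns).T
    eigengenes.index.name = "module"
    result = NetworkResult(beta=int(beta or 0), adjacency=None, tom=None,
                           module_labels=pd.Series(labels, index=norm.index,
                                                   name="module"),
                           eigengenes=eigengenes, merge_history=history)
    return result


def gene_significance(norm: pd.DataFrame, ctmax: np.ndarray) -> pd.DataFrame:
    """Signed Pearson correlation of each gene with CT_MAX plus a
    two-sided p-value from the t distribution with n-2 df."""
    y = np.asarray(ctmax, dtype=float)
    if y.size != norm.shape[1]:
        raise ValidationError("ctmax length must equal the number of samples")
    if y.size < 3:
        raise ValidationError("need at least 3 samples")
    if np.std(y) == 0:
        raise ValidationError("CT_MAX has zero variance")
    x = norm.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    if (sx == 0).any():
        raise ValidationError("zero-variance gene present; filter upstream")
    r = np.clip(xc @ yc / (sx * sy), -1.0, 1.0)
    n = y.size
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return pd.DataFrame({"gs": r, "p": p}, index=norm.index)


def select_candidates(gs_table: pd.DataFrame, module_labels: pd.Series,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg correction applied separately within each module
    (label 0 is its own group); candidates are genes with q < alpha and
    regulator_class is the sign of their gene significance."""
    table = gs_table.copy()
    table["module"] = module_labels.reindex(table.index).astype(int)
    if table["module"].isna().any():
        raise ValidationError("every gene needs a module label")
    q = np.empty(len(table))
    for _, idx in table.groupby("module").groups.items():
        pos = table.index.get_indexer(idx)
        q[pos] = bh_adjust(table["p"].to_numpy()[pos])
    table["q"] = q
    table["candidate"] = table["q"] < alpha
    table["regulator_class"] = np.where(table["gs"] >= 0, "positive", "negative")
    table.loc[~table["candidate"], "regulator_class"] = pd.NA
    return table


def validate_gs_subsets(gs_full: pd.DataFrame, gs_subset_a: pd.DataFrame,
                        gs_subset_b: pd.DataFrame,
                        candidate_ids) -> dict:
    """Cross-cohort consistency of gene significance over candidate genes.

    Compares the GS of two sample subsets (e.g. wild-caught vs
    common-garden) over the candidate set: OLS R^2, Spearman rank
    correlation, and per-regulator-class paired t-tests and R^2 (classes
    come from the full-cohort table).
    """
    ids = [g for g in candidate_ids
           if g in gs_subset_a.index and g in gs_subset_b.index]
    if len(ids) < 3:
        raise ValidationError("need at least 3 shared candidate genes")
    a = gs_subset_a.loc[ids, "gs"].to_numpy()
    b = gs_subset_b.loc[ids, "gs"].to_numpy()
    lin = sps.linregress(a, b)
    rho, rho_p = sps.spearmanr(a, b)
    report = {
        "n_candidates": len(ids),
        "r2": float(lin.rvalue ** 2),
        "slope": float(lin.slope),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "per_class": {},
    }
    classes = gs_full.loc[ids, "regulator_class"]
    for cls in ("positive", "negative"):
        sel = np.asarray(classes == cls)
        entry: dict = {"n": int(sel.sum())}
        if sel.sum() >= 3:
            if np.allclose(a[sel] - b[sel], (a[sel] - b[sel])[0]):
                entry["paired_t"] = {"t": 0.0 if np.allclose(a[sel], b[sel]) else np.nan,
                                     "p": np.nan}
            else:
                t_res = sps.ttest_rel(a[sel], b[sel])
                entry["paired_t"] = {"t": float(t_res.statistic),
                                     "p": float(t_res.pvalue)}
            lin_c = sps.linregress(a[sel], b[sel])
            entry["r2"] = float(lin_c.rvalue ** 2)
        report["per_class"][cls] = entry
    return report
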