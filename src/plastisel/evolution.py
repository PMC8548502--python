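"""Ancestral plasticity vs. evolved divergence, with a matrix-
randomization null.

Over the candidate genes, two log-fold-change vectors are computed from
common-garden samples:

* ancestral plasticity: forest 32 degC mean minus forest 25 degC mean
  (the forest lineage stands in for the pre-urban ancestral state);
* evolved divergence: urban 32 degC mean minus forest 32 degC mean.

Their Spearman rank correlation is negative when evolution reverses the
direction of ancestral plasticity. Because both contrasts share the
forest-32 group, sampling noise alone induces a negative correlation
(regression toward the mean); the null distribution is built by
permuting each gene's expression values independently across the
common-garden samples (preserving each gene's value multiset while
destroying group structure) and recomputing both contrasts and rho. The
one-sided empirical p asks whether the observed rho is more negative
than this artifact alone produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, ValidationError

__all__ = [
    "plasticity_divergence_lfcs",
    "spearman_correlation",
    "randomization_null_test",
    "RandomizationNull",
]


@dataclass
class RandomizationNull:
    observed_rho: float
    n_perm: int
    null_rhos: np.ndarray
    lower_limit: float   # 2.5th percentile
    upper_limit: float   # 97.5th percentile
    empirical_p: float
    seed: int
    scheme: str


def plasticity_divergence_lfcs(norm: pd.DataFrame, samples: pd.DataFrame,
                               candidate_ids) -> pd.DataFrame:
    """Ancestral-plasticity and evolved-divergence LFC vectors over the
    candidate genes, from common-garden samples."""
    from .expression import select_samples

    groups = {
        "forest25": dict(rearing="common_garden", habitat="forest", treatment="day25"),
        "forest32": dict(rearing="common_garden", habitat="forest", treatment="day32"),
        "urban32": dict(rearing="common_garden", habitat="urban", treatment="day32"),
    }
    idx = {}
    for name, clause in groups.items():
        ids = select_samples(samples, **clause)
        if len(ids) == 0:
            raise ValidationError(f"missing common-garden group: {name}")
        idx[name] = list(ids)
    ids = [g for g in candidate_ids if g in norm.index]
    if len(ids) != len(list(candidate_ids)):
        raise ValidationError("candidate genes absent from expression matrix")
    sub = norm.loc[ids]
    ancestral = sub[idx["forest32"]].mean(axis=1) - sub[idx["forest25"]].mean(axis=1)
    evolved = sub[idx["urban32"]].mean(axis=1) - sub[idx["forest32"]].mean(axis=1)
    out = pd.DataFrame({"ancestral_lfc": ancestral, "evolved_lfc": evolved})
    out["opposite_sign"] = np.sign(out["ancestral_lfc"]) * np.sign(out["evolved_lfc"]) < 0
    return out


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rho with mid-rank tie handling and the t-approximation
    p-value (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("rho undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _null_rhos(values: np.ndarray, i25, i32, iu32, n_perm: int,
               rng: np.random.Generator) -> np.ndarray:
    """Vectorized within-gene permutation null: each permutation shuffles
    every gene's values independently across the sample axis."""
    n_genes, n_samples = values.shape
    rhos = np.empty(n_perm)
    for b in range(n_perm):
        order = np.argsort(rng.random((n_genes, n_samples)), axis=1)
        perm = np.take_along_axis(values, order, axis=1)
        anc = perm[:, i32].mean(axis=1) - perm[:, i25].mean(axis=1)
        evo = perm[:, iu32].mean(axis=1) - perm[:, i32].mean(axis=1)
        ra = sps.rankdata(anc)
        re = sps.rankdata(evo)
        rhos[b] = np.corrcoef(ra, re)[0, 1]
    return rhos


def randomization_null_test(norm_candidates: pd.DataFrame,
                            samples: pd.DataFrame,
                            n_perm: int = 1000,
                            seed: int = 0,
                            scheme: str = "within_gene") -> RandomizationNull:
    """Matrix-randomization null for the plasticity-divergence rho.

    ``norm_candidates`` must be restricted to candidate genes x
    common-garden samples. Schemes: ``within_gene`` (default; permute each
    gene's values over samples), ``global`` (shuffle the whole matrix),
    ``within_sample`` (permute each column). The empirical p uses the
    add-one rule, one-sided toward "more negative than artifact":
    ``(1 + #{null <= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if scheme not in ("within_gene", "global", "within_sample"):
        raise ConfigurationError(f"unknown randomization scheme: {scheme}")
    cg = samples.loc[samples["rearing"] == "common_garden"]
    cols = [s for s in norm_candidates.columns if s in cg.index]
    if set(cols) != set(norm_candidates.columns):
        raise ValidationError("matrix must contain only common-garden samples")
    meta = cg.loc[norm_candidates.columns]
    i25 = np.flatnonzero((meta["habitat"] == "forest") & (meta["treatment"] == "day25"))
    i32 = np.flatnonzero((meta["habitat"] == "forest") & (meta["treatment"] == "day32"))
    iu32 = np.flatnonzero((meta["habitat"] == "urban") & (meta["treatment"] == "day32"))
    for name, ii in (("forest 25", i25), ("forest 32", i32), ("urban 32", iu32)):
        if ii.size == 0:
            raise ValidationError(f"missing common-garden group: {name}")
    values = norm_candidates.to_numpy(dtype=float)
    anc = values[:, i32].mean(axis=1) - values[:, i25].mean(axis=1)
    evo = values[:, iu32].mean(axis=1) - values[:, i32].mean(axis=1)
    observed, _ = spearman_correlation(anc, evo)

    rng = np.random.default_rng(seed)
    n_genes, n_samples = values.shape
    if scheme == "within_gene":
        rhos = _null_rhos(values, i25, i32, iu32, n_perm, rng)
    else:
        rhos = np.empty(n_perm)
        for b in range(n_perm):
            if scheme == "global":
                perm = rng.permutation(values.ravel()).reshape(values.shape)
            else:  # within_sample
                order = np.argsort(rng.random((n_samples, n_genes)), axis=1).T
                perm = np.take_along_axis(values, order, axis=0)
            a = perm[:, i32].mean(axis=1) - perm[:, i25].mean(axis=1)
            e = perm[:, iu32].mean(axis=1) - perm[:, i32].mean(axis=1)
            rhos[b] = np.corrcoef(sps.rankdata(a), sps.rankdata(e))[0, 1]
    empirical_p = (1.0 + np.sum(rhos <= observed)) / (n_perm + 1.0)
    lo, hi = np.percentile(rhos, [2.5, 97.5])
    return RandomizationNull(
        observed_rho=float(observed), n_perm=int(n_perm),
        null_rhos=rhos, lower_limit=float(lo), upper_limit=float(hi),
        empirical_p=float(empirical_p), seed=int(seed), scheme=scheme)
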