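"""Population-genomic divergence contrasts between plasticity classes.

Holds the SNP-level battery: quality/MAF/missingness filtering,
per-SNP Weir-Cockerham two-population theta (the AMOVA-family FST
estimator) with optional Gaussian-kernel position smoothing, empirical
FST-outlier enrichment against the transcriptome background, windowed
pairwise LD (unphased genotypic r^2) with distance binning and a
gene-block permutation test, Hardy-Weinberg deviation scans, and
annotation-class (nonsynonymous / noncoding) enrichment.

Genotypes are alt-allele dosages in an int8 matrix (SNPs x samples) with
-1 for missing. SNP annotations (position, gene, functional class,
plasticity set) live in a parallel DataFrame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, ValidationError
from .stats import hwe_chisquare, two_proportion_test, welch_t_test, wilson_interval

log = logging.getLogger(__name__)

__all__ = [
    "VariantTable",
    "filter_variants",
    "weir_cockerham_components",
    "weir_cockerham_theta",
    "multilocus_theta",
    "weir_cockerham_fst",
    "gaussian_smooth",
    "fst_outlier_enrichment",
    "mean_fst_contrast",
    "pairwise_ld",
    "ld_set_comparison",
    "hwe_scan",
    "annotation_class_enrichment",
]

MISSING = -1

FUNCTIONAL_CLASSES = ("nonsynonymous", "synonymous", "noncoding")


@dataclass
class VariantTable:
    """Biallelic SNP table: per-SNP annotations + dosage genotypes."""

    snps: pd.DataFrame          # snp_id, scaffold, pos, qual, gene_id, functional_class, set_label
    genotypes: np.ndarray       # (n_snps, n_samples) int8, -1 = missing
    sample_ids: list[str]

    def __post_init__(self):
        if self.genotypes.shape != (len(self.snps), len(self.sample_ids)):
            raise ValidationError("genotype matrix shape mismatch")
        g = self.genotypes
        if ((g < -1) | (g > 2)).any():
            raise ValidationError("genotypes must be dosages 0/1/2 or -1")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def take(self, mask_or_index) -> "VariantTable":
        snps = self.snps.loc[mask_or_index] if getattr(mask_or_index, "dtype", None) == bool \
            else self.snps.iloc[mask_or_index]
        pos = self.snps.index.get_indexer(snps.index)
        return replace(self, snps=snps.copy(), genotypes=self.genotypes[pos])

    def subset_samples(self, sample_ids) -> "VariantTable":
        idx = self.sample_indices(sample_ids)
        return replace(self, snps=self.snps.copy(),
                       genotypes=self.genotypes[:, idx],
                       sample_ids=list(sample_ids))

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown sample id {e.args[0]!r}") from e


def filter_variants(raw: VariantTable, min_qual: float = 20.0,
                    min_maf: float = 0.05,
                    max_missing: float = 0.20) -> tuple[VariantTable, dict]:
    """Retain biallelic SNPs with quality >= min_qual, minor-allele
    frequency >= min_maf (computed from non-missing genotypes over all
    samples, boundary inclusive), and missing fraction < max_missing.

    Returns the filtered table plus a report of removals per criterion
    (each counted against the raw table independently).
    """
    g = raw.genotypes
    n_samples = g.shape[1]
    miss_frac = (g == MISSING).sum(axis=1) / n_samples
    non_missing = (g != MISSING).sum(axis=1)
    alt = np.where(g == MISSING, 0, g).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(non_missing > 0, alt / (2.0 * non_missing), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    qual = raw.snps["qual"].to_numpy(dtype=float)
    pass_qual = qual >= min_qual
    pass_maf = maf >= min_maf  # NaN compares False: all-missing SNPs fail
    pass_miss = miss_frac < max_missing
    keep = pass_qual & pass_maf & pass_miss
    report = {
        "n_input": int(raw.n_snps),
        "n_retained": int(keep.sum()),
        "removed_quality": int((~pass_qual).sum()),
        "removed_maf": int((~pass_maf).sum()),
        "removed_missing": int((~pass_miss).sum()),
    }
    if report["n_retained"] == 0:
        log.warning("variant filter retained zero SNPs")
    return raw.take(np.flatnonzero(keep)), report


def weir_cockerham_components(genotypes: np.ndarray, idx_a: np.ndarray,
                              idx_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Weir-Cockerham (1984) two-population variance components.

    Returns ``(a, d)`` where ``a`` is the among-population component and
    ``d = a + b + c`` the total; the per-SNP estimate is ``a / d`` and the
    multi-locus estimate over a SNP set is ``sum(a) / sum(d)``. Entries are
    NaN where a population has < 2 non-missing genotypes or the pooled
    site is monomorphic.
    """
    g = genotypes
    ga, gb = g[:, idx_a], g[:, idx_b]
    stats = []
    for gp in (ga, gb):
        ok = gp != MISSING
        n = ok.sum(axis=1).astype(float)                   # individuals
        alt = np.where(ok, gp, 0).sum(axis=1).astype(float)
        het = np.where(ok, gp == 1, False).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
            h = het / n
        stats.append((n, p, h))
    (na, pa, ha), (nb, pb, hb) = stats
    valid = (na >= 2) & (nb >= 2)
    r = 2.0
    nbar = (na + nb) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (na ** 2 + nb ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (na * pa + nb * pb) / (r * nbar)
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (na * ha + nb * hb) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                     - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
        d = a + b + c
    polymorphic = (pbar > 0) & (pbar < 1) | (s2 > 0)
    usable = valid & polymorphic & np.isfinite(d) & (d != 0)
    a_out = np.full(g.shape[0], np.nan)
    d_out = np.full(g.shape[0], np.nan)
    a_out[usable] = a[usable]
    d_out[usable] = d[usable]
    return a_out, d_out


def weir_cockerham_theta(genotypes: np.ndarray, idx_a: np.ndarray,
                         idx_b: np.ndarray) -> np.ndarray:
    """Per-SNP Weir-Cockerham theta ``a / (a + b + c)``; missing genotypes
    dropped per SNP per population. Negative estimates are retained
    (clamping would bias set means); undefined sites are NaN.
    """
    a, d = weir_cockerham_components(genotypes, idx_a, idx_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        return a / d


def multilocus_theta(genotypes: np.ndarray, idx_a: np.ndarray,
                     idx_b: np.ndarray,
                     snp_mask: np.ndarray | None = None) -> float:
    """Multi-locus Weir-Cockerham estimate over a SNP set: the ratio of
    summed variance components, ``sum(a) / sum(a+b+c)``.

    This is the recommended set-level summary (nearly unbiased for the
    divergence parameter, unlike the mean of per-SNP ratios, which is
    biased toward zero by the per-locus ratio noise).
    """
    a, d = weir_cockerham_components(genotypes, idx_a, idx_b)
    if snp_mask is not None:
        a, d = a[snp_mask], d[snp_mask]
    ok = np.isfinite(a) & np.isfinite(d)
    if not ok.any() or d[ok].sum() == 0:
        return float("nan")
    return float(a[ok].sum() / d[ok].sum())


def gaussian_smooth(pos: np.ndarray, values: np.ndarray,
                    sigma_bp: float) -> np.ndarray:
    """Gaussian-kernel weighted mean of ``values`` over positions on one
    scaffold: w = exp(-d^2 / (2 sigma^2)). NaN values are excluded from
    every weighted mean."""
    pos = np.asarray(pos, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    out = np.full(values.shape, np.nan)
    if sigma_bp <= 0:
        out[ok] = values[ok]
        return out
    pos_ok = pos[ok]
    val_ok = values[ok]
    # chunked so the pairwise distance block stays modest for large scans
    chunk = max(1, int(2e7) // max(1, pos_ok.size))
    for start in range(0, pos.size, chunk):
        d = pos[start:start + chunk, None] - pos_ok[None, :]
        w = np.exp(-(d * d) / (2.0 * sigma_bp * sigma_bp))
        denom = w.sum(axis=1)
        good = denom > 0
        seg = np.full(d.shape[0], np.nan)
        seg[good] = (w[good] @ val_ok) / denom[good]
        out[start:start + chunk] = seg
    return out


def weir_cockerham_fst(variants: VariantTable, pop_a, pop_b,
                       sigma_bp: float | None = None) -> pd.DataFrame:
    """Per-SNP theta between two sample sets, with optional per-scaffold
    Gaussian smoothing. Returns a DataFrame indexed like the SNP table
    with columns theta (and smoothed if requested)."""
    ia = variants.sample_indices(pop_a)
    ib = variants.sample_indices(pop_b)
    if ia.size < 2 or ib.size < 2:
        raise ValidationError("need >= 2 samples per population")
    theta = weir_cockerham_theta(variants.genotypes, ia, ib)
    scan = pd.DataFrame({"theta": theta}, index=variants.snps.index)
    if sigma_bp is not None:
        smoothed = np.full(len(scan), np.nan)
        for _, idx in variants.snps.groupby("scaffold").groups.items():
            pos_idx = variants.snps.index.get_indexer(idx)
            smoothed[pos_idx] = gaussian_smooth(
                variants.snps["pos"].to_numpy()[pos_idx], theta[pos_idx], sigma_bp)
        scan["smoothed"] = smoothed
    return scan


def fst_outlier_enrichment(theta: pd.Series, set_index, background_index,
                           alpha: float = 0.05) -> dict:
    """Empirical FST-outlier enrichment: the threshold is the (1-alpha)
    quantile of the background theta distribution (type-7 interpolation);
    the focal set's outlier proportion is compared to the background's by
    a continuity-corrected two-proportion test."""
    bg = theta.loc[background_index].dropna()
    if len(bg) < 100:
        raise ValidationError("need >= 100 background SNPs")
    focal = theta.loc[set_index].dropna()
    if len(focal) == 0:
        raise ValidationError("empty focal SNP set")
    threshold = float(np.quantile(bg.to_numpy(), 1.0 - alpha))  # type-7 default
    n_out_focal = int((focal > threshold).sum())
    n_out_bg = int((bg > threshold).sum())
    test = two_proportion_test(n_out_focal, len(focal), n_out_bg, len(bg))
    return {
        "threshold": threshold,
        "alpha": alpha,
        "n_set": int(len(focal)),
        "n_outliers": n_out_focal,
        "outlier_proportion": n_out_focal / len(focal),
        "background_outlier_proportion": n_out_bg / len(bg),
        "expected_proportion": alpha,
        "chi2": test["chi2"],
        "p": test["p"],
        "quantile_type": "linear (type 7)",
    }


def mean_fst_contrast(theta: pd.Series, set_a_index, set_b_index) -> dict:
    """Welch t-test of per-SNP theta between two SNP sets (e.g.
    maladaptive vs adaptive), with means +/- SE as plotted."""
    a = theta.loc[set_a_index].dropna().to_numpy()
    b = theta.loc[set_b_index].dropna().to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 SNPs per set")
    res = welch_t_test(a, b)
    res["n_a"], res["n_b"] = int(a.size), int(b.size)
    res["se_a"] = float(a.std(ddof=1) / np.sqrt(a.size))
    res["se_b"] = float(b.std(ddof=1) / np.sqrt(b.size))
    return res


def pairwise_ld(variants: VariantTable, window_bp: int = 10_000,
                bin_bp: int = 1_000) -> pd.DataFrame:
    """Unphased genotypic r^2 for every SNP pair falling in the same
    non-overlapping window: squared Pearson correlation of dosages over
    samples non-missing at both SNPs. Windows are [k*w, (k+1)*w) on the
    1-based positions; distance bins are left-closed right-open multiples
    of ``bin_bp``. Pairs monomorphic among complete observations are
    skipped (count logged)."""
    snps = variants.snps
    g = variants.genotypes
    rows = []
    n_skipped = 0
    window = ((snps["pos"].to_numpy() - 1) // window_bp)
    for (scaffold, win), idx in snps.groupby(
            [snps["scaffold"], pd.Series(window, index=snps.index)]).groups.items():
        pos_idx = snps.index.get_indexer(idx)
        if pos_idx.size < 2:
            continue
        order = np.argsort(snps["pos"].to_numpy()[pos_idx], kind="stable")
        pos_idx = pos_idx[order]
        for ii in range(pos_idx.size - 1):
            for jj in range(ii + 1, pos_idx.size):
                i, j = pos_idx[ii], pos_idx[jj]
                gi, gj = g[i], g[j]
                ok = (gi != MISSING) & (gj != MISSING)
                if ok.sum() < 2:
                    n_skipped += 1
                    continue
                xi, xj = gi[ok].astype(float), gj[ok].astype(float)
                if xi.std() == 0 or xj.std() == 0:
                    n_skipped += 1
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                dist = int(snps["pos"].iloc[j] - snps["pos"].iloc[i])
                rows.append({
                    "scaffold": scaffold,
                    "window_id": int(win),
                    "snp_i": snps.index[i],
                    "snp_j": snps.index[j],
                    "gene_id": snps["gene_id"].iloc[i],
                    "set_label": snps["set_label"].iloc[i],
                    "distance_bp": dist,
                    "distance_bin": dist // bin_bp,
                    "r2": float(r * r),
                })
    if n_skipped:
        log.info("skipped %d monomorphic/undersampled SNP pairs", n_skipped)
    return pd.DataFrame(rows, columns=[
        "scaffold", "window_id", "snp_i", "snp_j", "gene_id", "set_label",
        "distance_bp", "distance_bin", "r2"])


def ld_set_comparison(pairs: pd.DataFrame, candidate_sets=("candidate_adaptive",
                                                           "candidate_maladaptive",
                                                           "candidate_unclassified"),
                      n_perm: int = 1000, seed: int = 0) -> dict:
    """Candidate-vs-background LD contrast.

    Reports per-distance-bin mean +/- SE of r^2 for each group and tests
    the overall mean-r^2 difference by gene-block permutation: gene labels
    (candidate vs background) are shuffled across genes ``n_perm`` times,
    preserving the within-gene dependence of pairs. One-sided empirical p
    for candidate LD exceeding background (add-one rule). The original
    study fit a crossed-random-effects linear mixed model; that metadata
    is recorded in the report.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if pairs.empty:
        raise ValidationError("no SNP pairs provided")
    is_cand = pairs["set_label"].isin(candidate_sets).to_numpy()
    if is_cand.all() or not is_cand.any():
        raise ValidationError("need pairs in both candidate and background sets")
    r2 = pairs["r2"].to_numpy(dtype=float)

    def bin_profile(mask):
        sub = pairs.loc[mask]
        prof = sub.groupby("distance_bin")["r2"].agg(["mean", "sem", "count"])
        return {int(b): {"mean": float(m), "se": float(s) if np.isfinite(s) else None,
                         "n": int(c)}
                for b, (m, s, c) in prof.iterrows()}

    observed = float(r2[is_cand].mean() - r2[~is_cand].mean())
    genes = pairs["gene_id"].to_numpy()
    gene_ids, gene_inv = np.unique(genes, return_inverse=True)
    gene_is_cand = np.zeros(gene_ids.size, dtype=bool)
    for k in range(gene_ids.size):
        gene_is_cand[k] = is_cand[gene_inv == k][0]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(gene_is_cand)
        mask = perm[gene_inv]
        if mask.all() or not mask.any():
            continue
        diff = r2[mask].mean() - r2[~mask].mean()
        if diff >= observed:
            exceed += 1
    empirical_p = (1.0 + exceed) / (n_perm + 1.0)
    return {
        "mean_r2_candidate": float(r2[is_cand].mean()),
        "mean_r2_background": float(r2[~is_cand].mean()),
        "difference": observed,
        "empirical_p": float(empirical_p),
        "n_perm": int(n_perm),
        "seed": int(seed),
        "bins_candidate": bin_profile(is_cand),
        "bins_background": bin_profile(~is_cand),
        "reference_method": "crossed-random-effects linear mixed model "
                            "(replaced by gene-block permutation)",
    }


def hwe_scan(variants: VariantTable, pops: dict, alpha: float = 0.05,
             candidate_sets=("candidate_adaptive", "candidate_maladaptive",
                             "candidate_unclassified")) -> tuple[pd.DataFrame, dict]:
    """Per-SNP, per-population Hardy-Weinberg chi-square scan plus a
    candidate-vs-background comparison of deviant proportions.

    ``pops`` maps population name -> list of sample ids. Returns the long
    HWE table and a per-population equality-of-proportions report.
    """
    rows = []
    for pop_name, sample_ids in pops.items():
        idx = variants.sample_indices(sample_ids)
        sub = variants.genotypes[:, idx]
        for i, snp_id in enumerate(variants.snps.index):
            gi = sub[i]
            ok = gi != MISSING
            if ok.sum() == 0:
                continue
            n_aa = int((gi[ok] == 0).sum())
            n_ab = int((gi[ok] == 1).sum())
            n_bb = int((gi[ok] == 2).sum())
            res = hwe_chisquare(n_aa, n_ab, n_bb)
            rows.append({
                "snp_id": snp_id, "pop": pop_name,
                "n_hom_ref": n_aa, "n_het": n_ab, "n_hom_alt": n_bb,
                "chi2": res["chi2"], "p": res["p"],
                "deviant": res["p"] < alpha,
                "low_count": res["low_count"],
                "set_label": variants.snps["set_label"].iloc[i],
            })
    table = pd.DataFrame(rows)
    comparison = {}
    for pop_name, sub in table.groupby("pop"):
        cand = sub[sub["set_label"].isin(candidate_sets)]
        bg = sub[~sub["set_label"].isin(candidate_sets)]
        if len(cand) and len(bg):
            test = two_proportion_test(int(cand["deviant"].sum()), len(cand),
                                       int(bg["deviant"].sum()), len(bg))
            comparison[pop_name] = {
                "prop_deviant_candidate": test["prop_a"],
                "prop_deviant_background": test["prop_b"],
                "chi2": test["chi2"], "p": test["p"],
                "n_candidate": len(cand), "n_background": len(bg),
            }
    return table, comparison


def annotation_class_enrichment(variants: VariantTable, focal_set: str,
                                functional_class: str,
                                background_set: str = "background") -> dict:
    """Enrichment of a functional class (nonsynonymous or noncoding) in a
    focal SNP set relative to the transcriptome background: continuity-
    corrected two-proportion chi-square plus a Wilson 95% CI on the focal
    proportion."""
    if functional_class not in FUNCTIONAL_CLASSES:
        raise ConfigurationError(f"unknown functional class: {functional_class}")
    snps = variants.snps
    if snps["functional_class"].isna().any():
        raise ValidationError("functional class missing for some SNPs")
    focal = snps[snps["set_label"] == focal_set]
    bg = snps[snps["set_label"] == background_set]
    if len(focal) == 0 or len(bg) == 0:
        raise ValidationError("focal or background SNP set is empty")
    k_f = int((focal["functional_class"] == functional_class).sum())
    k_b = int((bg["functional_class"] == functional_class).sum())
    test = two_proportion_test(k_f, len(focal), k_b, len(bg))
    lo, hi = wilson_interval(k_f, len(focal))
    return {
        "functional_class": functional_class,
        "focal_set": focal_set,
        "n_focal": int(len(focal)),
        "n_background": int(len(bg)),
        "prop_focal": test["prop_a"],
        "prop_background": test["prop_b"],
        "chi2": test["chi2"],
        "p": test["p"],
        "ci95_focal": (lo, hi),
    }
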