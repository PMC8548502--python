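"""Seeded synthetic datasets with planted ground truth.

The generator emulates the study design the analysis stages assume: a
wild cohort sampled from paired forest/urban sites in four Puerto Rican
municipalities plus a common-garden cohort from Mayaguez, a continuous
heat-tolerance phenotype (CT_MAX, degC), negative-binomial RNA-seq
counts with a planted candidate-gene signal, and biallelic SNP
genotypes with Balding-Nichols habitat divergence, within-gene linkage
disequilibrium, and planted functional-class composition per SNP set.

Planted structure (defaults):

* CT_MAX drawn first (truncated normal, mean 39, sd 1.5, bounds 35-43);
  candidate-gene log2 expression is coupled to standardized CT_MAX with
  strength ``gs_coupling`` times the gene's regulator sign, so the
  gene-significance screen is directly exercised. Wild urban animals get
  a +0.82 degC CT_MAX shift (the habitat effect seen in the wild).
* Heat-induced reaction norms: candidate genes shift by
  ``lfc_magnitude`` log2 units between 25 and 32 degC in the forest
  lineage, in a direction that opposes the regulator sign for a fraction
  ``forest_maladaptive_fraction`` of candidates; urban norms are
  attenuated by ``urban_attenuation`` and reversed with probability
  ``urban_reversal_prob``.
* Genes are tiled on one synthetic scaffold (100 kb spacing, 10 kb
  span); SNP allele frequencies follow the Balding-Nichols Beta model
  with the divergence parameter set per SNP set (so expected FST equals
  the planted value), and within-gene LD is induced by comonotone
  haplotype coupling with set-specific strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .popgen import MISSING, VariantTable

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_expression_dataset",
    "generate_variant_dataset",
]

MUNICIPALITIES = ("Aguadilla", "Arecibo", "Mayaguez", "SanJuan")
TREATMENTS = ("night15", "day25", "day32")
# multiplier applied to the heat reaction norm per acclimation treatment
TREATMENT_NORM_SCALE = {"night15": -0.5, "day25": 0.0, "day32": 1.0}

# wild sample sizes (municipality, habitat); the Mayaguez row excludes the
# common-garden animals so the wild cohort totals 114
DEFAULT_WILD_SIZES = {
    ("Aguadilla", "forest"): 11, ("Aguadilla", "urban"): 16,
    ("Arecibo", "forest"): 18, ("Arecibo", "urban"): 16,
    ("Mayaguez", "forest"): 12, ("Mayaguez", "urban"): 9,
    ("SanJuan", "forest"): 11, ("SanJuan", "urban"): 21,
}
# common-garden split; the alternative published split (forest 4/3) is
# config-selectable
DEFAULT_COMMON_GARDEN_SIZES = {
    ("forest", "day25"): 3, ("forest", "day32"): 4,
    ("urban", "day25"): 5, ("urban", "day32"): 4,
}

SET_LABELS = ("background", "candidate_adaptive", "candidate_maladaptive")


@dataclass
class GeneratorConfig:
    n_genes: int = 5000
    n_candidates: int = 600
    n_modules: int = 7
    wild_sizes: dict = field(default_factory=lambda: dict(DEFAULT_WILD_SIZES))
    common_garden_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_COMMON_GARDEN_SIZES))
    common_garden_municipality: str = "Mayaguez"

    # phenotype
    ctmax_mean: float = 39.0
    ctmax_sd: float = 1.5
    ctmax_bounds: tuple = (35.0, 43.0)
    wild_urban_ctmax_shift: float = 0.82

    # expression model (log2 scale)
    log2_mean_loc: float = 5.0
    log2_mean_scale: float = 1.5
    dispersion_log_mean: float = -3.0   # lognormal gene-wise NB dispersion
    dispersion_log_sd: float = 0.5
    module_effect_sd: float = 0.5
    gs_coupling: float = 0.5            # log2 units per SD of CT_MAX
    lfc_magnitude: float = 1.5          # forest 25->32 shift, log2 units
    forest_maladaptive_fraction: float = 0.8
    urban_attenuation: float = 0.5
    urban_reversal_prob: float = 0.5

    # variants
    n_snps: int = 20_000
    gene_span_bp: int = 10_000
    gene_spacing_bp: int = 100_000
    scaffold: str = "scaffold_1"
    missing_rate: float = 0.05
    planted_fst: dict = field(default_factory=lambda: {
        "background": 0.02,
        "candidate_adaptive": 0.06,
        "candidate_maladaptive": 0.12,
    })
    class_proportions: dict = field(default_factory=lambda: {
        # (nonsynonymous, synonymous, noncoding) per SNP set
        "background": (0.15, 0.35, 0.50),
        "candidate_adaptive": (0.30, 0.20, 0.50),
        "candidate_maladaptive": (0.10, 0.20, 0.70),
    })
    ld_coupling: dict = field(default_factory=lambda: {
        "background": 0.3,
        "candidate_adaptive": 0.8,
        "candidate_maladaptive": 0.8,
    })
    qual_range: tuple = (25.0, 60.0)

    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_candidates <= 0:
            raise ConfigurationError("gene counts must be positive")
        if self.n_candidates > self.n_genes:
            raise ConfigurationError("n_candidates exceeds n_genes")
        if self.n_snps <= 0 or self.n_modules <= 0:
            raise ConfigurationError("n_snps and n_modules must be positive")
        for sizes in (self.wild_sizes, self.common_garden_sizes):
            if any(v <= 0 for v in sizes.values()):
                raise ConfigurationError("group sample sizes must be positive")
        for label, f in self.planted_fst.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(
                    f"planted_fst[{label!r}] must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.urban_attenuation <= 1.0:
            raise ConfigurationError("urban_attenuation must lie in [0, 1]")
        if not 0.0 <= self.urban_reversal_prob <= 1.0:
            raise ConfigurationError("urban_reversal_prob must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded alongside every generated dataset."""

    candidate_gene_ids: list
    regulator_sign: dict            # gene_id -> +1 / -1
    forest_norm_direction: dict     # gene_id -> +1 / -1 (25->32 sign)
    urban_norm_direction: dict
    set_label: dict                 # gene_id -> SNP-set label for every gene
    urban_attenuation: float
    urban_reversal_prob: float
    planted_fst: dict
    class_proportions: dict
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _make_metadata(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for (muni, habitat), n in sorted(config.wild_sizes.items()):
        for k in range(n):
            rows.append({
                "municipality": muni, "habitat": habitat, "rearing": "wild",
                # acclimation treatments cycle so each site covers all three
                "treatment": TREATMENTS[k % 3],
            })
    for (habitat, treatment), n in sorted(config.common_garden_sizes.items()):
        for _ in range(n):
            rows.append({
                "municipality": config.common_garden_municipality,
                "habitat": habitat, "rearing": "common_garden",
                "treatment": treatment,
            })
    meta = pd.DataFrame(rows)
    meta.index = [f"S{i:04d}" for i in range(len(meta))]
    meta.index.name = "sample_id"

    lo, hi = config.ctmax_bounds
    shift = np.where((meta["rearing"] == "wild") & (meta["habitat"] == "urban"),
                     config.wild_urban_ctmax_shift, 0.0)
    mean = config.ctmax_mean + shift
    a = (lo - mean) / config.ctmax_sd
    b = (hi - mean) / config.ctmax_sd
    meta["ctmax_C"] = sps.truncnorm.rvs(a, b, loc=mean, scale=config.ctmax_sd,
                                        random_state=rng)
    return meta


def generate_expression_dataset(config: GeneratorConfig
                                ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (sample metadata, count matrix, truth).

    Counts are negative-binomial with gene-wise lognormal dispersion; the
    log2 mean of a candidate gene is baseline + module effect +
    gs_coupling * z(CT_MAX) * regulator_sign + the treatment-by-lineage
    reaction-norm term. Non-candidate genes carry only baseline + module
    structure and are independent of CT_MAX.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _make_metadata(config, rng)
    n_samples = len(meta)
    n_genes = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]

    cand_pos = np.sort(rng.choice(n_genes, size=config.n_candidates, replace=False))
    is_cand = np.zeros(n_genes, dtype=bool)
    is_cand[cand_pos] = True
    sign = np.where(rng.random(n_genes) < 0.5, 1, -1)
    maladaptive = rng.random(n_genes) < config.forest_maladaptive_fraction
    forest_dir = np.where(maladaptive, -sign, sign)
    reversed_urban = rng.random(n_genes) < config.urban_reversal_prob
    urban_dir = np.where(reversed_urban, -forest_dir, forest_dir)

    base = rng.normal(config.log2_mean_loc, config.log2_mean_scale, size=n_genes)
    dispersion = np.exp(rng.normal(config.dispersion_log_mean,
                                   config.dispersion_log_sd, size=n_genes))
    module = rng.integers(1, config.n_modules + 1, size=n_genes)
    loading = config.module_effect_sd * rng.uniform(0.5, 1.5, size=n_genes)
    factors = rng.normal(size=(config.n_modules + 1, n_samples))
    # Module factors model design-independent co-regulation: the planted
    # reaction norms and the CT_MAX coupling carry all structured signal.
    # Chance correlation of a shared factor with the phenotype or with a
    # design cell would otherwise masquerade as signal (mass-producing
    # spurious candidates or biasing group contrasts), so the factors are
    # residualized against the design-group dummies and CT_MAX exactly.
    group_codes = (meta["rearing"].astype(str) + "/" + meta["habitat"].astype(str)
                   + "/" + meta["treatment"].astype(str))
    dummies = pd.get_dummies(group_codes).to_numpy(dtype=float)
    design = np.column_stack([dummies, meta["ctmax_C"].to_numpy()])
    q, _ = np.linalg.qr(design)
    factors -= (factors @ q) @ q.T
    factors -= factors.mean(axis=1, keepdims=True)
    factors /= factors.std(axis=1, keepdims=True)

    # GS coupling uses CT_MAX deviations from the (rearing, habitat,
    # treatment) group mean: group-level expression/CT_MAX structure is
    # carried by the planted reaction norms, so coupling raw CT_MAX would
    # double-count it and confound the 25->32 contrasts in small groups
    ct = meta["ctmax_C"]
    z = (ct - ct.groupby([meta["rearing"], meta["habitat"],
                          meta["treatment"]]).transform("mean")).to_numpy()
    z = z / z.std()
    tscale = meta["treatment"].map(TREATMENT_NORM_SCALE).to_numpy()
    is_urban = (meta["habitat"] == "urban").to_numpy()
    norm_dir = np.where(is_urban[None, :], urban_dir[:, None], forest_dir[:, None])
    norm_mag = np.where(is_urban, config.lfc_magnitude * (1 - config.urban_attenuation),
                        config.lfc_magnitude)

    log2_mean = base[:, None] + loading[:, None] * factors[module, :]
    log2_mean = log2_mean + is_cand[:, None] * (
        config.gs_coupling * sign[:, None] * z[None, :]
        + norm_dir * (tscale * norm_mag)[None, :])

    mu = np.exp2(log2_mean)
    size = 1.0 / dispersion[:, None]
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    counts_df = pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                             columns=pd.Index(meta.index.to_list()))
    counts_df.index.name = "gene_id"

    cand_ids = [gene_ids[i] for i in cand_pos]
    set_label = {}
    for i, gid in enumerate(gene_ids):
        if not is_cand[i]:
            set_label[gid] = "background"
        elif maladaptive[i]:
            set_label[gid] = "candidate_maladaptive"
        else:
            set_label[gid] = "candidate_adaptive"
    truth = SyntheticTruth(
        candidate_gene_ids=cand_ids,
        regulator_sign={g: int(sign[i]) for i, g in enumerate(gene_ids) if is_cand[i]},
        forest_norm_direction={g: int(forest_dir[i]) for i, g in enumerate(gene_ids)
                               if is_cand[i]},
        urban_norm_direction={g: int(urban_dir[i]) for i, g in enumerate(gene_ids)
                              if is_cand[i]},
        set_label=set_label,
        urban_attenuation=config.urban_attenuation,
        urban_reversal_prob=config.urban_reversal_prob,
        planted_fst=dict(config.planted_fst),
        class_proportions={k: tuple(v) for k, v in config.class_proportions.items()},
        seed=int(config.seed),
    )
    return meta, counts_df, truth


def gene_coordinates(config: GeneratorConfig, gene_ids) -> pd.DataFrame:
    """Genes tiled along one synthetic scaffold: gene i spans
    [i*spacing+1, i*spacing+span] in 1-based coordinates."""
    starts = np.arange(len(gene_ids)) * config.gene_spacing_bp + 1
    return pd.DataFrame({
        "scaffold": config.scaffold,
        "start": starts,
        "end": starts + config.gene_span_bp - 1,
    }, index=pd.Index(gene_ids, name="gene_id"))


def _habitat_frequencies(p_anc: np.ndarray, fst: np.ndarray,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols: habitat frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F).
    F=0 keeps the ancestral frequency; F>=1 plants opposite fixed alleles
    (random orientation) so the fixation limit is exact."""
    out = []
    orient = rng.random(p_anc.size) < 0.5
    for which in (0, 1):
        freq = p_anc.copy()
        drift = fst > 0
        mild = drift & (fst < 1)
        if mild.any():
            shape = (1.0 - fst[mild]) / fst[mild]
            freq[mild] = rng.beta(p_anc[mild] * shape, (1 - p_anc[mild]) * shape)
        fixed = fst >= 1
        if fixed.any():
            freq[fixed] = np.where(orient[fixed], float(which), 1.0 - which)
        out.append(freq)
    return out[0], out[1]


def generate_variant_dataset(config: GeneratorConfig, truth: SyntheticTruth,
                             samples: pd.DataFrame) -> VariantTable:
    """Biallelic SNP genotypes for every sample, with planted habitat
    divergence, within-gene LD, functional classes, and missingness.

    An independent random stream (seed + 1) is used so expression and
    variant generation can be re-run separately yet reproducibly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = list(truth.set_label.keys())
    coords = gene_coordinates(config, gene_ids)
    n_genes = len(gene_ids)

    per_gene = np.full(n_genes, config.n_snps // n_genes)
    per_gene[: config.n_snps % n_genes] += 1
    if (per_gene > config.gene_span_bp).any():
        raise ConfigurationError("more SNPs per gene than basepairs in span")

    sample_ids = list(samples.index)
    is_urban = (samples["habitat"] == "urban").to_numpy()
    n_samples = len(sample_ids)

    snp_rows = []
    geno_blocks = []
    class_labels = np.array(["nonsynonymous", "synonymous", "noncoding"])
    snp_counter = 0
    for gi, gid in enumerate(gene_ids):
        m = int(per_gene[gi])
        if m == 0:
            continue
        label = truth.set_label[gid]
        fst = truth.planted_fst.get(label, 0.0)
        start = int(coords["start"].iloc[gi])
        offsets = np.sort(rng.choice(config.gene_span_bp, size=m, replace=False))
        pos = start + offsets
        p_anc = rng.uniform(0.1, 0.9, size=m)
        p_forest, p_urban = _habitat_frequencies(
            p_anc, np.full(m, float(fst)), rng)
        p_sample = np.where(is_urban[None, :], p_urban[:, None], p_forest[:, None])

        # two haplotypes per sample; with probability ld_coupling a
        # haplotype is comonotone across the gene's SNPs (shared latent
        # uniform), inducing within-gene LD while preserving marginals
        c = config.ld_coupling.get(label, 0.0)
        geno = np.zeros((m, n_samples), dtype=np.int8)
        for _hap in range(2):
            shared_u = rng.random(n_samples)
            indep_u = rng.random((m, n_samples))
            comonotone = rng.random(n_samples) < c
            u = np.where(comonotone[None, :], shared_u[None, :], indep_u)
            geno += (u < p_sample).astype(np.int8)
        if config.missing_rate > 0:
            miss = rng.random((m, n_samples)) < config.missing_rate
            geno[miss] = MISSING

        probs = np.asarray(config.class_proportions.get(label, (0.15, 0.35, 0.5)),
                           dtype=float)
        probs = probs / probs.sum()
        fclass = class_labels[rng.choice(3, size=m, p=probs)]
        qual = np.round(rng.uniform(*config.qual_range, size=m), 2)
        for j in range(m):
            snp_rows.append({
                "snp_id": f"snp{snp_counter:06d}",
                "scaffold": config.scaffold,
                "pos": int(pos[j]),
                "qual": float(qual[j]),
                "gene_id": gid,
                "functional_class": fclass[j],
                "set_label": label,
            })
            snp_counter += 1
        geno_blocks.append(geno)

    snps = pd.DataFrame(snp_rows).set_index("snp_id")
    genotypes = np.vstack(geno_blocks)
    return VariantTable(snps=snps, genotypes=genotypes, sample_ids=sample_ids)
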