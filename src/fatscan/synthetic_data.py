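"""Synthetic genotypes, QTL architectures and fatty-acid phenotypes.

The generator emulates the statistical design the analysis assumes — a
commercial 50K-style SNP panel on ~2,000 sire-family beef cattle — at a
configurable desk scale: biallelic dosages with uniform-drawn allele
frequencies (optionally with first-order LD between adjacent SNPs),
evenly spaced map positions giving a fixed SNP count per 1-Mb window, a
sparse QTL architecture concentrated in designated windows, contemporary
group and covariate fixed effects, and normal residuals sized to hit a
target heritability.  Multi-trait profiles share QTL positions with
correlated (pleiotropic) effects.  All randomness flows from one seed via
``numpy.random.default_rng`` substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fatty_acid_traits import FATTY_ACIDS, to_fat_percent
from .io_config import COVARIATE_COLUMNS, GenotypeMatrix, MarkerMap, TraitTable
from .window_gwas import assign_windows

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_trait",
           "simulate_correlated_traits", "simulate_fa_profiles",
           "TABLE1_BEEF_MEANS", "TABLE1_BEEF_SDS"]


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    ``qtl_spec`` lists ``(window_id, n_qtl, fraction_of_genetic_variance)``
    triples; fractions must sum to at most 1.  Defaults give 20 SNPs per
    1-Mb window (the 50K-panel density, ~53k SNPs over ~2,650 Mb) across
    29 autosomes, MAF uniform on [0.05, 0.5], 10 contemporary groups and
    four unit-variance covariates with modest coefficients.
    """

    n_animals: int = 500
    n_snps: int = 1_000
    n_chromosomes: int = 29
    snps_per_window: int = 20
    window_size_bp: int = 1_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    frac_unmapped: float = 0.0
    qtl_spec: list[tuple[str, int, float]] = field(default_factory=list)
    h2_target: float = 0.5
    n_contemporary_groups: int = 10
    sigma_cg: float = 0.5
    covariate_coefs: tuple[float, ...] = (0.1, 0.1, 0.1, 0.1)
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError("h2_target must lie in (0, 1)")
        if sum(f for _, _, f in self.qtl_spec) > 1.0 + 1e-12:
            raise ValueError("QTL variance fractions exceed 1")
        if not -1.0 < self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in (-1, 1)")


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    u_true: np.ndarray
    g_true: np.ndarray
    h2: float
    sigma2_g: float
    sigma2_e: float
    window_fractions: dict[str, float]
    cg_effects: dict[str, float]
    covariate_coefs: tuple[float, ...]


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, stream]))


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, MarkerMap]:
    """Dosage matrix plus marker map under the configured design.

    Per SNP the B-allele frequency is Uniform(maf_range) and each animal
    draws Binomial(2, p) — independently across SNPs for ``ld_rho`` = 0,
    or with a first-order haplotype-copying process (each of the two
    gametes copies its allele at the previous SNP with probability
    ``ld_rho``) to mimic LD.  Positions are evenly spaced so every 1-Mb
    window holds ``snps_per_window`` SNPs; SNPs that do not divide evenly
    across chromosomes go to the last chromosome.  A ``frac_unmapped``
    fraction of SNPs (chosen at random) loses its map position.
    """
    rng = _rng(cfg.seed, 1)
    m, n = cfg.n_snps, cfg.n_animals
    p = rng.uniform(*cfg.maf_range, size=m)

    if cfg.ld_rho == 0.0:
        dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    else:
        hap = np.empty((2 * n, m), dtype=np.int8)
        hap[:, 0] = rng.random(2 * n) < p[0]
        for j in range(1, m):
            copy = rng.random(2 * n) < cfg.ld_rho
            fresh = rng.random(2 * n) < p[j]
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        dosages = (hap[0::2] + hap[1::2]).astype(float)

    animal_ids = [f"an{i:05d}" for i in range(n)]
    snp_ids = [f"snp{j:06d}" for j in range(m)]

    per_chrom = m // cfg.n_chromosomes
    spacing = cfg.window_size_bp // cfg.snps_per_window
    chroms: list[str | None] = []
    pos: list[float] = []
    for j in range(m):
        c = min(j // per_chrom, cfg.n_chromosomes - 1) if per_chrom else \
            cfg.n_chromosomes - 1
        k = j - c * per_chrom
        chroms.append(str(c + 1))
        pos.append(float(k * spacing))
    if cfg.frac_unmapped > 0:
        unmapped = rng.choice(m, size=int(round(cfg.frac_unmapped * m)),
                              replace=False)
        for j in unmapped:
            chroms[j] = None
            pos[j] = np.nan
    mmap = MarkerMap(pd.DataFrame(
        {"snp_id": snp_ids, "chrom": chroms, "pos_bp": pos}))
    return GenotypeMatrix(animal_ids, snp_ids, dosages), mmap


def simulate_trait(genos: GenotypeMatrix, mmap: MarkerMap, cfg: SimConfig,
                   trait_name: str = "trait") -> tuple[TraitTable, SimTruth]:
    """Single phenotype from the linear model y = Xb + Zu + e.

    QTL effects are drawn normal within the designated windows (zero
    elsewhere) and rescaled so each window contributes its specified
    fraction of a unit total genetic variance; residuals are rescaled so
    the realized heritability var(g)/(var(g)+var(e)) equals ``h2_target``
    exactly in-sample.
    """
    traits, truths = simulate_correlated_traits(
        genos, mmap, cfg, trait_names=[trait_name],
        effect_corr=np.ones((1, 1)))
    return traits[trait_name], truths[trait_name]


def simulate_correlated_traits(
        genos: GenotypeMatrix, mmap: MarkerMap, cfg: SimConfig,
        trait_names: list[str], effect_corr: np.ndarray
) -> tuple[dict[str, TraitTable], dict[str, SimTruth]]:
    """Multiple traits sharing QTL positions with correlated effects.

    ``effect_corr`` is the across-trait correlation matrix of per-QTL
    effects (pleiotropy); each trait gets its own fixed effects and
    residuals at the same ``h2_target``.
    """
    rng = _rng(cfg.seed, 2)
    Z = genos.dosages
    if np.isnan(Z).any():
        raise ValueError("impute missing dosages before simulating traits")
    n, m = Z.shape
    T = len(trait_names)
    effect_corr = np.asarray(effect_corr, dtype=float)
    if effect_corr.shape != (T, T):
        raise ValueError("effect_corr must be (n_traits, n_traits)")

    wmap = assign_windows(mmap, cfg.window_size_bp)
    Zc = Z - Z.mean(axis=0)

    u_true = np.zeros((T, m))
    window_contrib = {}
    chol = np.linalg.cholesky(effect_corr + 1e-12 * np.eye(T))
    for window, n_qtl, frac in cfg.qtl_spec:
        if window not in wmap.members:
            raise ValueError(f"QTL window {window!r} has no SNPs in the map")
        idx = wmap.members[window]
        if n_qtl > idx.size:
            raise ValueError(f"window {window!r} holds {idx.size} SNPs, "
                             f"fewer than the {n_qtl} QTL requested")
        chosen = rng.choice(idx, size=n_qtl, replace=False)
        raw = chol @ rng.standard_normal((T, n_qtl))   # correlated effects
        for t in range(T):
            w = Zc[:, chosen] @ raw[t]
            v = w.var(ddof=1)
            scale = np.sqrt(frac / v) if v > 0 else 0.0
            u_true[t, chosen] += raw[t] * scale
        window_contrib[window] = frac

    traits_out: dict[str, TraitTable] = {}
    truths: dict[str, SimTruth] = {}
    groups = rng.integers(0, cfg.n_contemporary_groups, size=n)
    covs = rng.standard_normal((n, len(COVARIATE_COLUMNS)))
    for t, name in enumerate(trait_names):
        rt = _rng(cfg.seed, 10 + t)
        g = Zc @ u_true[t]
        var_g = g.var(ddof=1)
        sigma2_e = var_g * (1.0 - cfg.h2_target) / cfg.h2_target \
            if var_g > 0 else 1.0
        e = rt.standard_normal(n)
        e = (e - e.mean()) / e.std(ddof=1) * np.sqrt(sigma2_e)
        cg_eff = rt.normal(0.0, cfg.sigma_cg, size=cfg.n_contemporary_groups)
        coefs = np.asarray(cfg.covariate_coefs, dtype=float)
        y = cfg.mu + cg_eff[groups] + covs @ coefs + g + e
        tab = pd.DataFrame({
            "animal_id": genos.animal_ids,
            "contemporary_group": [f"cg{k}" for k in groups],
            **{c: covs[:, i] for i, c in enumerate(COVARIATE_COLUMNS)},
            name: y,
        })
        fr = {w: (Zc[:, wmap.members[w]] @ u_true[t][wmap.members[w]]
                  ).var(ddof=1) / var_g if var_g > 0 else 0.0
              for w in window_contrib}
        realized_h2 = var_g / (var_g + e.var(ddof=1)) if var_g > 0 else 0.0
        traits_out[name] = TraitTable(tab)
        truths[name] = SimTruth(
            u_true=u_true[t].copy(), g_true=g, h2=realized_h2,
            sigma2_g=var_g, sigma2_e=sigma2_e, window_fractions=fr,
            cg_effects={f"cg{k}": cg_eff[k]
                        for k in range(cfg.n_contemporary_groups)},
            covariate_coefs=tuple(coefs))
    return traits_out, truths


# ---------------------------------------------------------------------------
# fatty-acid composition profiles
# ---------------------------------------------------------------------------

#: published per-acid means and SDs on the beef basis (g x 1e-5 per g meat),
#: the default magnitudes the profile generator reproduces.
TABLE1_BEEF_MEANS: dict[str, float] = {
    "10:0": 1.96, "12:0": 3.59, "13:0": 0.27, "14:0": 160.34, "14:1": 33.32,
    "15:0": 33.84, "16:0": 1558.61, "16:1": 206.06, "17:0": 81.07,
    "17:1": 64.24, "18:0": 790.43, "cis-9 18:1": 2281.82,
    "cis-11 18:1": 5.89, "cis-12 18:1": 15.59, "cis-13 18:1": 5.87,
    "trans-6/9 18:1": 8.09, "trans-10/11 18:1": 212.59,
    "trans-12 18:1": 3.98, "trans-15 18:1": 61.99, "18:2": 217.59,
    "18:3n3": 10.52, "18:3n6": 0.88, "20:0": 1.10, "20:1": 4.88,
    "20:2": 2.07, "20:3n3": 1.49, "20:3n6": 7.25, "20:4": 41.38,
    "20:5": 6.80, "22:0": 5.45, "22:1": 0.30, "22:4": 3.18, "22:5": 7.5,
    "22:6": 4.02, "23:0": 3.54, "24:0": 7.27, "CLAc9t11": 7.32,
    "CLAt10c12": 3.32,
}
TABLE1_BEEF_SDS: dict[str, float] = {
    "10:0": 2.72, "12:0": 3.38, "13:0": 0.57, "14:0": 73.46, "14:1": 17.45,
    "15:0": 18.79, "16:0": 596.70, "16:1": 92.83, "17:0": 42.57,
    "17:1": 34.59, "18:0": 292.08, "cis-9 18:1": 923.99,
    "cis-11 18:1": 6.93, "cis-12 18:1": 13.05, "cis-13 18:1": 7.47,
    "trans-6/9 18:1": 12.48, "trans-10/11 18:1": 119.07,
    "trans-12 18:1": 10.09, "trans-15 18:1": 39.95, "18:2": 70.66,
    "18:3n3": 11.19, "18:3n6": 2.32, "20:0": 1.95, "20:1": 5.99,
    "20:2": 2.87, "20:3n3": 5.48, "20:3n6": 8.88, "20:4": 16.37,
    "20:5": 12.89, "22:0": 7.03, "22:1": 3.20, "22:4": 6.71, "22:5": 8.81,
    "22:6": 7.43, "23:0": 8.11, "24:0": 17.32, "CLAc9t11": 8.29,
    "CLAt10c12": 5.06,
}


def simulate_fa_profiles(n_animals: int, seed: int = 0,
                         means: dict[str, float] | None = None,
                         sds: dict[str, float] | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal fatty-acid profiles on both bases.

    Each acid's beef-basis weight is log-normal with the given mean and
    SD (defaults: the published magnitudes), independent across acids;
    the fat-percent table is the closure of the beef table to 100.
    Closure induces the mild negative correlation real compositions show.
    Returns ``(beef_df, fat_percent_df)`` indexed by animal id.
    """
    means = dict(TABLE1_BEEF_MEANS if means is None else means)
    sds = dict(TABLE1_BEEF_SDS if sds is None else sds)
    if any(v <= 0 for v in means.values()):
        raise ValueError("non-positive mean fatty-acid weight")
    rng = _rng(seed, 3)
    names = [n for n in FATTY_ACIDS if n in means]
    cols = {}
    for name in names:
        mu, sd = means[name], sds.get(name, 0.0)
        if sd <= 0:
            cols[name] = np.full(n_animals, mu)
            continue
        s2 = np.log1p((sd / mu) ** 2)
        cols[name] = rng.lognormal(np.log(mu) - s2 / 2.0, np.sqrt(s2),
                                   size=n_animals)
    beef = pd.DataFrame(cols,
                        index=[f"an{i:05d}" for i in range(n_animals)])
    beef.index.name = "animal_id"
    return beef, to_fat_percent(beef)
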