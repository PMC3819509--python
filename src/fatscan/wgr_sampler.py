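"""Spike-and-slab Bayesian whole-genome regression (BayesB / BayesC).

Model, fitted one trait at a time::

    y = X b + Z u + e,    e ~ N(0, sigma2_e I)

* ``y`` — phenotypes; ``X`` — fixed effects (population mean, contemporary
  group, four centered covariates) with a flat prior;
* ``Z`` — allele dosages (copies of the B allele, 0/1/2);
* ``u_j`` — marker effects under a mixture prior: zero with probability
  ``pi``, otherwise normal with variance ``sigma2_uj`` drawn from a scaled
  inverse chi-square prior — a single common variance under BayesC, a
  locus-specific variance under BayesB;
* ``sigma2_e`` — residual variance, scaled inverse chi-square prior.

Sampling is single-site Gibbs.  Marker inclusion is sampled with the effect
integrated out given the current slab variance, then the effect from its
normal full conditional; BayesB locus variances are refreshed from their
scaled-inverse-chi-square full conditional (included loci) or the prior
(excluded loci), which leaves the same stationary distribution as the
classical Metropolis scheme with the prior as proposal.  The inner loop is
JIT-compiled with numba.

Per stored sample the genetic variance ``sigma2_g`` is the across-animal
variance of Zu; heritability is the ratio of posterior means
``mean(sigma2_g) / (mean(sigma2_g) + mean(sigma2_e))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .io_config import (COVARIATE_COLUMNS, RunConfig, TraitTable, logger)

__all__ = [
    "MixturePrior", "PosteriorChain", "PosteriorSummary", "build_design",
    "elicit_priors_bayesC", "run_chain", "summarize", "dgv",
    "save_chain", "load_chain",
]


@dataclass
class MixturePrior:
    """Prior for the marker-effect mixture and the residual variance."""

    pi: float
    nu_u: float = 4.0
    s2_u: float = 1e-4
    nu_e: float = 10.0
    s2_e: float = 1.0
    variant: str = "BayesB"  # or "BayesC"
    #: set to hold a variance fixed (no Gibbs update) — used for oracle tests
    fix_marker_variance: bool = False
    fix_residual_variance: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0,1]")
        if self.nu_u <= 2 or self.nu_e <= 2:
            raise ValueError("prior degrees of freedom must exceed 2")
        if self.s2_u <= 0 or self.s2_e <= 0:
            raise ValueError("prior scales must be positive")
        if self.variant not in ("BayesB", "BayesC"):
            raise ValueError("variant must be BayesB or BayesC")


@dataclass
class PosteriorChain:
    """Thinned post-burn-in MCMC samples."""

    u: np.ndarray          # (n_stored, m) marker effects (exact zeros kept)
    b: np.ndarray          # (n_stored, p) fixed effects
    sigma2_e: np.ndarray   # (n_stored,)
    sigma2_g: np.ndarray   # (n_stored,) across-animal variance of Zu
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sigma2_g < 0).any():
            raise ValueError("negative genetic-variance sample")

    @property
    def n_stored(self) -> int:
        return self.u.shape[0]

    @property
    def n_markers(self) -> int:
        return self.u.shape[1]

    def inclusion_counts(self) -> np.ndarray:
        """Number of nonzero marker effects per stored sample."""
        return (self.u != 0).sum(axis=1)


@dataclass
class PosteriorSummary:
    u_hat: np.ndarray
    b_hat: np.ndarray
    sigma2_g: float
    sigma2_e: float
    h2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 outside [0,1]")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(traits: TraitTable, trait: str,
                 covariates: tuple[str, ...] = COVARIATE_COLUMNS,
                 ) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Response and fixed-effect design for one trait.

    Animals with a missing phenotype, contemporary group or covariate are
    dropped (count logged, mirroring exclusion of incomplete records).
    X = intercept ("population mean") + contemporary-group indicators with
    one level dropped + centered covariates; full column rank.

    Returns ``(y, X, kept_animal_ids, n_dropped)``.
    """
    df = traits.table
    covariates = tuple(c for c in covariates if c in df.columns)
    needed = [trait, "contemporary_group", *covariates]
    complete = df[needed].notna().all(axis=1) & \
        (df["contemporary_group"].astype(str) != "")
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("%d animals removed for incomplete records; %d analyzed",
                    n_dropped, int(complete.sum()))
    sub = df[complete]
    if sub.empty:
        raise ValueError("no animals with complete records")
    y = sub[trait].to_numpy(dtype=float)

    groups = sub["contemporary_group"].astype(str)
    sizes = groups.value_counts()
    if (sizes == 1).any():
        logger.warning("%d singleton contemporary groups", int((sizes == 1).sum()))
    dummies = pd.get_dummies(groups, drop_first=True, dtype=float)
    cols = [np.ones(len(sub))]
    if not dummies.empty:
        cols.append(dummies.to_numpy())
    for c in covariates:
        v = sub[c].to_numpy(dtype=float)
        cols.append((v - v.mean())[:, None])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    return y, X, sub["animal_id"].astype(str).tolist(), n_dropped


# ---------------------------------------------------------------------------
# Gibbs kernel (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs(Zt, Xt, y, pi, nu_u, s2_u, nu_e, s2_e, bayesb,
           fix_s2u, fix_s2e, n_iter, n_burn, thin, seed,
           u_store, b_store, s2e_store, s2g_store):
    np.random.seed(seed)
    m, n = Zt.shape
    p = Xt.shape[0]
    c = np.empty(m)
    for j in range(m):
        c[j] = np.dot(Zt[j], Zt[j])
    xtx = np.empty(p)
    for l in range(p):
        xtx[l] = np.dot(Xt[l], Xt[l])

    b = np.zeros(p)
    u = np.zeros(m)
    s2_uj = np.full(m, s2_u)          # BayesB locus variances
    s2u_common = s2_u                 # BayesC slab variance
    sigma2_e = s2_e
    r = y.copy()
    log_prior_odds = 0.0
    if 0.0 < pi < 1.0:
        log_prior_odds = np.log((1.0 - pi) / pi)
    store_idx = 0
    g = np.zeros(n)

    for it in range(n_iter):
        # --- fixed effects, flat prior ---
        for l in range(p):
            xl = Xt[l]
            rhs = np.dot(xl, r) + xtx[l] * b[l]
            mean = rhs / xtx[l]
            new = mean + np.random.standard_normal() * np.sqrt(sigma2_e / xtx[l])
            diff = b[l] - new
            if diff != 0.0:
                for i in range(n):
                    r[i] += xl[i] * diff
                b[l] = new

        # --- marker effects ---
        k_in = 0
        ssq = 0.0
        for j in range(m):
            s2j = s2_uj[j] if bayesb else s2u_common
            zj = Zt[j]
            cj = c[j]
            rhs = np.dot(zj, r) + cj * u[j]
            include = False
            if pi >= 1.0:
                include = False
            elif cj == 0.0:
                # monomorphic after centering: data carry no information
                include = pi <= 0.0 or np.random.random() < (1.0 - pi)
            else:
                v = cj * s2j + sigma2_e
                log_bf = 0.5 * (np.log(sigma2_e / v)
                                + rhs * rhs * s2j / (sigma2_e * v))
                if pi <= 0.0:
                    include = True
                else:
                    logit = log_prior_odds + log_bf
                    if logit > 35.0:
                        include = True
                    elif logit < -35.0:
                        include = False
                    else:
                        include = np.random.random() < 1.0 / (1.0 + np.exp(-logit))
            if include:
                denom = cj + sigma2_e / s2j
                if denom <= 0.0:
                    new_u = 0.0
                else:
                    mean = rhs / denom
                    new_u = mean + np.random.standard_normal() * \
                        np.sqrt(sigma2_e / denom)
                k_in += 1
            else:
                new_u = 0.0
            diff = u[j] - new_u
            if diff != 0.0:
                for i in range(n):
                    r[i] += zj[i] * diff
                u[j] = new_u
            if bayesb and not fix_s2u:
                if new_u != 0.0:
                    s2_uj[j] = (nu_u * s2_u + new_u * new_u) / \
                        np.random.chisquare(nu_u + 1.0)
                else:
                    s2_uj[j] = nu_u * s2_u / np.random.chisquare(nu_u)
            elif include:
                ssq += new_u * new_u

        # --- variance components ---
        if (not bayesb) and (not fix_s2u):
            s2u_common = (nu_u * s2_u + ssq) / np.random.chisquare(nu_u + k_in)
        if not fix_s2e:
            sse = np.dot(r, r)
            sigma2_e = (nu_e * s2_e + sse) / np.random.chisquare(nu_e + n)

        # --- storage ---
        if it >= n_burn and (it - n_burn + 1) % thin == 0:
            for i in range(n):
                g[i] = 0.0
            for j in range(m):
                if u[j] != 0.0:
                    uj = u[j]
                    zj = Zt[j]
                    for i in range(n):
                        g[i] += zj[i] * uj
            gm = 0.0
            for i in range(n):
                gm += g[i]
            gm /= n
            s2g = 0.0
            for i in range(n):
                d = g[i] - gm
                s2g += d * d
            s2g = s2g / (n - 1) if n > 1 else 0.0
            u_store[store_idx] = u
            b_store[store_idx] = b
            s2e_store[store_idx] = sigma2_e
            s2g_store[store_idx] = s2g
            store_idx += 1
    return store_idx


def run_chain(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
              prior: MixturePrior, cfg: RunConfig) -> PosteriorChain:
    """Run the Gibbs sampler; returns thinned post-burn-in samples.

    ``Z`` holds raw dosages; columns are centered internally (the intercept
    absorbs the shift, and genetic variance across animals is translation
    invariant), while stored effects apply unchanged to raw dosages.
    """
    y = np.ascontiguousarray(y, dtype=float)
    X = np.ascontiguousarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if y.shape[0] != n or X.shape[0] != n:
        raise ValueError("y, X, Z dimensions not conformable")
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotype")
    Zt = np.ascontiguousarray((Z - Z.mean(axis=0)).T)

    n_stored = cfg.n_stored
    u_store = np.zeros((n_stored, m))
    b_store = np.zeros((n_stored, X.shape[1]))
    s2e_store = np.zeros(n_stored)
    s2g_store = np.zeros(n_stored)
    stored = _gibbs(
        Zt, np.ascontiguousarray(X.T), y,
        float(prior.pi), float(prior.nu_u), float(prior.s2_u),
        float(prior.nu_e), float(prior.s2_e), prior.variant == "BayesB",
        prior.fix_marker_variance, prior.fix_residual_variance,
        cfg.n_iter, cfg.n_burn, cfg.thin, int(cfg.seed) % (2 ** 31),
        u_store, b_store, s2e_store, s2g_store,
    )
    assert stored == n_stored
    if not np.isfinite(s2e_store).all() or not np.isfinite(u_store).all():
        bad = int(np.argmax(~np.isfinite(s2e_store)))
        raise FloatingPointError(
            f"non-finite state at stored sample {bad}; aborting")
    return PosteriorChain(u_store, b_store, s2e_store, s2g_store,
                          thin=cfg.thin, seed=cfg.seed)


# ---------------------------------------------------------------------------
# prior elicitation (BayesC preliminary run)
# ---------------------------------------------------------------------------

def _scales_from_variances(sigma2_g: float, sigma2_e: float, pi: float,
                           sum2pq: float, nu_u: float, nu_e: float
                           ) -> tuple[float, float]:
    """Convert genetic/residual variances to mixture prior scales.

    The per-marker slab scale spreads the genetic variance over the
    expected ``(1-pi) * sum_j 2 p_j (1-p_j)`` contributing dosage variance:
    ``s2_u = sigma2_g (nu_u-2)/nu_u / ((1-pi) sum 2pq)``.
    """
    floor = 1e-8
    if sigma2_g <= 0:
        logger.warning("non-positive genetic variance %.3g; flooring slab "
                       "scale", sigma2_g)
    denom = max((1.0 - pi) * sum2pq, floor)
    s2_u = max(sigma2_g, floor) * (nu_u - 2.0) / nu_u / denom
    s2_e = max(sigma2_e, floor) * (nu_e - 2.0) / nu_e
    return s2_u, s2_e


def elicit_priors_bayesC(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                         cfg: RunConfig
                         ) -> tuple[MixturePrior, "PosteriorSummary"]:
    """Preliminary BayesC run that sets the BayesB prior scales.

    The BayesC chain uses prior genetic and residual variances each equal
    to half the phenotypic variance and ``pi`` = ``cfg.elicit_pi`` (0.95).
    Its posterior-mean variances become the BayesB scale parameters (at
    ``cfg.pi``), and its heritability is the trait's heritability estimate.
    """
    y = np.asarray(y, dtype=float)
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("degenerate (constant) phenotype")
    p = np.asarray(Z, dtype=float).mean(axis=0) / 2.0
    sum2pq = float(np.sum(2.0 * p * (1.0 - p)))
    s2_u0, s2_e0 = _scales_from_variances(
        vary / 2.0, vary / 2.0, cfg.elicit_pi, sum2pq, cfg.nu_u, cfg.nu_e)
    prior_c = MixturePrior(pi=cfg.elicit_pi, nu_u=cfg.nu_u, s2_u=s2_u0,
                           nu_e=cfg.nu_e, s2_e=s2_e0, variant="BayesC")
    sub = RunConfig(pi=cfg.elicit_pi, n_iter=cfg.elicit_n_iter,
                    n_burn=cfg.elicit_n_burn, thin=cfg.elicit_thin,
                    nu_u=cfg.nu_u, nu_e=cfg.nu_e, seed=cfg.seed,
                    basis=cfg.basis)
    chain = run_chain(y, X, Z, prior_c, sub)
    summary = summarize(chain)
    s2_u, s2_e = _scales_from_variances(
        summary.sigma2_g, summary.sigma2_e, cfg.pi, sum2pq, cfg.nu_u, cfg.nu_e)
    prior_b = MixturePrior(pi=cfg.pi, nu_u=cfg.nu_u, s2_u=s2_u,
                           nu_e=cfg.nu_e, s2_e=s2_e, variant="BayesB")
    return prior_b, summary


# ---------------------------------------------------------------------------
# posterior summaries and DGV
# ---------------------------------------------------------------------------

def summarize(chain: PosteriorChain) -> PosteriorSummary:
    """Posterior means; zeros are included when averaging marker effects."""
    if chain.n_stored == 0:
        raise ValueError("empty chain")
    sg = float(chain.sigma2_g.mean())
    se = float(chain.sigma2_e.mean())
    h2 = sg / (sg + se) if sg + se > 0 else 0.0
    return PosteriorSummary(
        u_hat=chain.u.mean(axis=0), b_hat=chain.b.mean(axis=0),
        sigma2_g=sg, sigma2_e=se, h2=h2)


def dgv(dosages: np.ndarray, u_hat: np.ndarray) -> np.ndarray:
    """Direct genomic breeding values: DGV_i = sum_j z_ij * u_hat_j."""
    Z = np.asarray(dosages, dtype=float)
    u_hat = np.asarray(u_hat, dtype=float)
    if Z.shape[1] != u_hat.shape[0]:
        raise ValueError(
            f"{Z.shape[1]} SNP columns but {u_hat.shape[0]} marker effects")
    return Z @ u_hat


# ---------------------------------------------------------------------------
# chain persistence
# ---------------------------------------------------------------------------

def save_chain(chain: PosteriorChain, path: str | Path) -> None:
    np.savez_compressed(path, u=chain.u, b=chain.b, sigma2_e=chain.sigma2_e,
                        sigma2_g=chain.sigma2_g,
                        meta=np.array([chain.thin, chain.seed]))


def load_chain(path: str | Path) -> PosteriorChain:
    with np.load(path) as data:
        thin, seed = (int(v) for v in data["meta"])
        return PosteriorChain(data["u"], data["b"], data["sigma2_e"],
                              data["sigma2_g"], thin=thin, seed=seed)
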