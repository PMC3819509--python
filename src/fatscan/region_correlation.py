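"""Within-window DGV correlations between trait pairs (pleiotropy probe).

Traits are fitted in separate chains; stored samples are paired by index
to form a pseudo-joint posterior.  For a window ``w`` and traits A, B the
correlation is the posterior mean of the across-animal covariance of the
two window DGVs, normalized by the square roots of the posterior-mean
window variances — so a window whose effects move the two traits in
lockstep scores near +1 and in opposition near −1.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .wgr_sampler import PosteriorChain
from .window_gwas import WindowMap

__all__ = ["window_dgv_samples", "region_correlation", "correlation_report"]


def window_dgv_samples(chain: PosteriorChain, dosages: np.ndarray,
                       member_idx: np.ndarray) -> np.ndarray:
    """Centered window DGV per stored sample: (n_stored, n_animals)."""
    member_idx = np.asarray(member_idx, dtype=np.int64)
    if member_idx.size == 0:
        raise ValueError("window has no member SNPs")
    Z = np.asarray(dosages, dtype=float)
    W = chain.u[:, member_idx] @ Z[:, member_idx].T
    return W - W.mean(axis=1, keepdims=True)


def region_correlation(chain_a: PosteriorChain, chain_b: PosteriorChain,
                       dosages: np.ndarray, member_idx: np.ndarray
                       ) -> float:
    """Within-window DGV correlation between two traits.

    numerator: mean over paired samples of the across-animal covariance;
    denominator: sqrt of the product of posterior-mean window variances.
    Returns NaN when either trait shows no variance in the window; the
    result is clamped to [-1, 1] against rounding.
    """
    if chain_a.n_stored != chain_b.n_stored:
        raise ValueError("chains store different sample counts")
    Wa = window_dgv_samples(chain_a, dosages, member_idx)
    Wb = window_dgv_samples(chain_b, dosages, member_idx)
    n = Wa.shape[1]
    if n < 2:
        raise ValueError("need >=2 animals")
    cov = (Wa * Wb).sum(axis=1) / (n - 1)
    var_a = (Wa ** 2).sum(axis=1) / (n - 1)
    var_b = (Wb ** 2).sum(axis=1) / (n - 1)
    denom = np.sqrt(var_a.mean() * var_b.mean())
    if denom == 0:
        return float("nan")
    return float(np.clip(cov.mean() / denom, -1.0, 1.0))


def correlation_report(chains: dict[str, PosteriorChain],
                       dosages: np.ndarray, wmap: WindowMap,
                       windows: list[str], traits: list[str] | None = None
                       ) -> pd.DataFrame:
    """Long-format table of within-window correlations for trait pairs."""
    traits = traits or list(chains)
    rows = []
    for w in windows:
        idx = wmap.members[w]
        for a, b in itertools.combinations_with_replacement(traits, 2):
            rows.append({
                "window": w, "trait_a": a, "trait_b": b,
                "correlation": region_correlation(
                    chains[a], chains[b], dosages, idx),
            })
    return pd.DataFrame(rows)
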