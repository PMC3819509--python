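"""1-Mb window association: per-window genetic variance and PPI.

SNPs are binned into consecutive megabase windows per chromosome
(``floor(position_bp / window_size)``); unmapped SNPs form one extra
window.  For every stored MCMC sample the window breeding values
``wDGV_i = sum_{j in w} z_ij u_j`` are computed across animals; the
across-animal variance of the window DGV, as a fraction of the same
sample's total-DGV variance, averaged over samples, is the window's
percentage of genetic variance.  The posterior probability of inclusion
(PPI) is the fraction of stored samples in which at least one member SNP
has a nonzero effect; windows with PPI strictly above the threshold
(default 0.90) are reported as QTL windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import MarkerMap, logger
from .wgr_sampler import PosteriorChain

UNMAPPED = "unmapped"

__all__ = ["WindowMap", "assign_windows", "window_variances",
           "significant_windows", "UNMAPPED"]


@dataclass
class WindowMap:
    """Window id per SNP plus member-index lookup."""

    snp_ids: list[str]
    window_ids: list[str]          # parallel to snp_ids, e.g. "19_51"
    members: dict[str, np.ndarray]  # window id -> SNP column indices

    def __post_init__(self) -> None:
        total = sum(len(v) for v in self.members.values())
        if total != len(self.snp_ids):
            raise ValueError("windows do not partition the SNPs")


def assign_windows(mmap: MarkerMap, window_size_bp: int = 1_000_000
                   ) -> WindowMap:
    """Bin SNPs into per-chromosome megabase windows.

    Window labels are ``{chrom}_{floor(pos/window_size)}`` (so FASN at
    51,384,922 bp on BTA19 falls in window ``19_51``); SNPs without a
    mapped position share the ``unmapped`` window.
    """
    tab = mmap.table
    ids = []
    for chrom, pos in zip(tab["chrom"], tab["pos_bp"]):
        if chrom is None or (isinstance(chrom, float) and np.isnan(chrom)) \
                or pd.isna(pos):
            ids.append(UNMAPPED)
        else:
            ids.append(f"{chrom}_{int(pos) // int(window_size_bp)}")
    members: dict[str, list[int]] = {}
    for j, w in enumerate(ids):
        members.setdefault(w, []).append(j)
    return WindowMap(
        snp_ids=tab["snp_id"].astype(str).tolist(),
        window_ids=ids,
        members={w: np.asarray(v, dtype=np.int64) for w, v in members.items()},
    )


def window_ppi(chain: PosteriorChain, member_idx: np.ndarray) -> float:
    """Fraction of stored samples with >=1 nonzero effect in the window."""
    return float((chain.u[:, member_idx] != 0).any(axis=1).mean())


def window_variances(chain: PosteriorChain, dosages: np.ndarray,
                     wmap: WindowMap) -> pd.DataFrame:
    """Per-window percent of genetic variance and PPI over stored samples.

    The variance fraction is formed per sample (window-DGV variance over
    total-DGV variance for the same stored effect vector) and then
    averaged; samples whose total genetic variance is zero carry no
    information about the partition and are skipped, with the skipped
    count reported.
    """
    Z = np.asarray(dosages, dtype=float)
    if Z.shape[1] != chain.n_markers:
        raise ValueError("genotype columns do not match chain markers")
    U = chain.u                                   # (S, m)
    G = U @ Z.T                                   # (S, n) total DGV
    total_var = G.var(axis=1, ddof=1)             # per stored sample
    ok = total_var > 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("%d stored samples had zero total genetic variance and "
                    "were skipped in window fractions", n_skipped)

    rows = []
    for w, idx in wmap.members.items():
        Gw = U[:, idx] @ Z[:, idx].T
        wvar = Gw.var(axis=1, ddof=1)
        frac = np.nan if not ok.any() else float(
            (wvar[ok] / total_var[ok]).mean())
        ppi = float((U[:, idx] != 0).any(axis=1).mean())
        order = np.sort(idx)
        rows.append({
            "window": w,
            "start_snp": wmap.snp_ids[order[0]],
            "end_snp": wmap.snp_ids[order[-1]],
            "n_snps": len(idx),
            "genetic_variance_pct": 100.0 * frac if np.isfinite(frac) else np.nan,
            "ppi": ppi,
            "n_samples_skipped": n_skipped,
        })
    return pd.DataFrame(rows)


def significant_windows(summaries: pd.DataFrame, threshold: float = 0.90
                        ) -> pd.DataFrame:
    """QTL windows: PPI strictly greater than the threshold, sorted by
    genetic variance (descending), the presentation order of the study."""
    if summaries.empty:
        return summaries
    sel = summaries[summaries["ppi"] > threshold]
    return sel.sort_values("genetic_variance_pct", ascending=False,
                           na_position="last").reset_index(drop=True)
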