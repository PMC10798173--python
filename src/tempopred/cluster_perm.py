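"""One-sample cluster-based sign-flip permutation test on 2-D binned maps.

For each jointly valid bin a one-sample t-test against zero is computed
across participants.  Bins with two-sided p <= 0.05 form cluster candidates;
candidates of the same sign that are 4-neighbour adjacent on the bin lattice
merge into clusters whose statistic is the sum of member t-values.  The
reference distribution is built from 1000 random sign-flips of each
participant's whole map (identity flip included); per permutation the signed
statistic of the most extreme cluster is recorded.  Observed clusters are
significant when their statistic falls below the 2.5th or above the 97.5th
percentile of this signed reference distribution.  Sign flipping is a valid
exchangeability argument for a one-sample test of zero mean because the null
distribution of each participant's map is assumed symmetric about zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "one_sample_tmap",
    "find_clusters",
    "permutation_test",
]

# rook adjacency: no diagonals
_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class Cluster:
    member_bins: list[tuple[int, int]]  # (mean-axis index, std-axis index)
    stat: float
    sign: int  # +1 or -1
    p: float | None = None
    significant: bool | None = None


@dataclass
class ClusterTestResult:
    tmap: np.ndarray
    pmap: np.ndarray
    mask: np.ndarray
    clusters: list[Cluster]
    perm_stats: np.ndarray
    n_perm: int
    seed: int | None
    alpha_form: float
    quantiles: tuple[float, float] = field(default=(np.nan, np.nan))


def one_sample_tmap(
    data: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin one-sample t against zero across participants.

    ``data`` is (participants, ...) with NaN outside the mask.  Returns
    (t, p, zero_variance): NaN outside the mask; zero-variance bins carry
    t = +/-inf with p = 0 (flagged) so they are treated as supra-threshold
    with the sign of their mean, and t = NaN when the mean is also zero.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    if mask is None:
        mask = ~np.isnan(data).any(axis=0)
    mean = np.full(data.shape[1:], np.nan)
    sd = np.full(data.shape[1:], np.nan)
    mean[mask] = data[:, mask].mean(axis=0)
    sd[mask] = data[:, mask].std(axis=0, ddof=1)
    zero_var = mask & (sd == 0)
    t = np.full(data.shape[1:], np.nan)
    p = np.full(data.shape[1:], np.nan)
    ok = mask & (sd > 0)
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    t[zero_var] = np.sign(mean[zero_var]) * np.inf
    t[zero_var & (mean == 0)] = np.nan
    p[zero_var] = 0.0
    return t, p, zero_var


def find_clusters(
    tmap: np.ndarray,
    pmap: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.05,
) -> list[Cluster]:
    """Connected components of same-sign supra-threshold bins (rook adjacency)."""
    clusters: list[Cluster] = []
    supra = mask & (pmap <= alpha) & ~np.isnan(tmap)
    for sign in (1, -1):
        signed = supra & (np.sign(tmap) == sign)
        labels, n_lab = ndimage.label(signed, structure=_STRUCTURE)
        for lab in range(1, n_lab + 1):
            members = [tuple(ij) for ij in np.argwhere(labels == lab)]
            stat = float(np.sum(tmap[labels == lab]))
            clusters.append(Cluster(member_bins=members, stat=stat, sign=sign))
    return clusters


def _extreme_stat(clusters: list[Cluster]) -> float:
    """Signed statistic of the most extreme cluster (0 if none)."""
    if not clusters:
        return 0.0
    return max((c.stat for c in clusters), key=abs)


def permutation_test(
    data: np.ndarray,
    mask: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha_form: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    reference: str = "signed_pooled",
) -> ClusterTestResult:
    """Sign-flip cluster permutation test on (participants, n_mean, n_std) data.

    ``reference='signed_pooled'`` records, per permutation, the signed
    statistic of the most extreme cluster and declares observed clusters
    significant outside the 2.5/97.5 percentiles; ``'max_abs'`` uses the
    classical max-|stat| null with a 95th-percentile cut.  Both control the
    two-sided family-wise error at 5%.  The identity permutation is included
    and cluster p-values carry the +1 rank correction, so p >= 1/(n_perm+1).
    """
    data = np.asarray(data, dtype=float)
    n_sub = data.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 participants")
    if reference not in ("signed_pooled", "max_abs"):
        raise ValueError("reference must be 'signed_pooled' or 'max_abs'")
    if rng is None:
        rng = np.random.default_rng(seed)
    if mask is None:
        mask = ~np.isnan(data).any(axis=0)
    grid_shape = data.shape[1:]
    flat = data[:, mask]  # (n_sub, n_bins)
    n_bins = flat.shape[1]
    if n_bins == 0:
        raise ValueError("empty mask")

    # Sum of squares per bin is invariant under sign flips.
    ss = np.sum(flat**2, axis=0)
    signs = np.where(rng.random((n_perm, n_sub)) < 0.5, 1.0, -1.0)
    signs[0] = 1.0  # identity permutation included
    means = signs @ flat / n_sub
    var = (ss[None, :] - n_sub * means**2) / (n_sub - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmat = means / np.sqrt(var / n_sub)
    tcrit = stats.t.ppf(1.0 - alpha_form / 2.0, df=n_sub - 1)
    # zero-variance bins: +/-inf t -> always supra-threshold, per convention
    supra_mat = np.abs(tmat) >= tcrit

    def grid_clusters(t_row: np.ndarray, supra_row: np.ndarray) -> list[Cluster]:
        tgrid = np.full(grid_shape, np.nan)
        tgrid[mask] = t_row
        pgrid = np.full(grid_shape, np.nan)
        pgrid[mask] = np.where(supra_row, 0.0, 1.0)  # thresholded proxy
        return find_clusters(tgrid, pgrid, mask, alpha=0.5)

    perm_stats = np.empty(n_perm)
    for k in range(n_perm):
        cl = grid_clusters(tmat[k], supra_mat[k])
        if reference == "signed_pooled":
            perm_stats[k] = _extreme_stat(cl)
        else:
            perm_stats[k] = max((abs(c.stat) for c in cl), default=0.0)

    # observed map with exact p-values
    tmap, pmap, _zv = one_sample_tmap(data, mask)
    observed = find_clusters(tmap, pmap, mask, alpha=alpha_form)
    if reference == "signed_pooled":
        lo, hi = np.percentile(perm_stats, [2.5, 97.5])
        for c in observed:
            if c.stat > 0:
                r = (1 + np.sum(perm_stats >= c.stat)) / (n_perm + 1)
            else:
                r = (1 + np.sum(perm_stats <= c.stat)) / (n_perm + 1)
            c.p = float(min(1.0, 2.0 * r))
            c.significant = bool(c.stat > hi or c.stat < lo)
        quantiles = (float(lo), float(hi))
    else:
        hi = np.percentile(perm_stats, 95.0)
        for c in observed:
            c.p = float((1 + np.sum(perm_stats >= abs(c.stat))) / (n_perm + 1))
            c.significant = bool(abs(c.stat) > hi)
        quantiles = (np.nan, float(hi))
    return ClusterTestResult(
        tmap=tmap,
        pmap=pmap,
        mask=mask,
        clusters=observed,
        perm_stats=perm_stats,
        n_perm=n_perm,
        seed=seed,
        alpha_form=alpha_form,
        quantiles=quantiles,
    )


def result_to_records(result: ClusterTestResult, mean_centers=None, std_centers=None) -> dict:
    """JSON-ready summary of a cluster test."""
    ii, jj = np.nonzero(result.mask)
    recs = [
        {
            "i": int(i),
            "j": int(j),
            "mean_center": None if mean_centers is None else float(mean_centers[i]),
            "std_center": None if std_centers is None else float(std_centers[j]),
            "t": float(result.tmap[i, j]),
            "p": float(result.pmap[i, j]),
        }
        for i, j in zip(ii, jj)
    ]
    clusters = [
        {
            "bins": [[int(i), int(j)] for i, j in c.member_bins],
            "stat": c.stat,
            "sign": c.sign,
            "p": c.p,
            "significant": c.significant,
        }
        for c in result.clusters
    ]
    return {
        "tmap": recs,
        "clusters": clusters,
        "n_perm": result.n_perm,
        "seed": result.seed,
        "alpha_form": result.alpha_form,
        "reference_quantiles": list(result.quantiles),
    }
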