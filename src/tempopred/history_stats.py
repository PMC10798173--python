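"""Local temporal statistics of the SOA stream preceding each target.

For a target at trial ``i`` the "N previous SOAs" are the SOAs of trials
``i, i-1, ..., i-N+1`` — the window includes the interval immediately
preceding the target, so ``mean_1`` equals the last SOA.  Local means are
computed for N in 1..7 and local STDs (sample, n-1 denominator) for N in
2..7.  Targets never occur before trial 11, so at least 10 preceding SOAs
always exist.

Per-participant 2-D performance maps bin targets by (local mean, local STD)
with overlapping sliding windows: mean centers 400..600 ms, half-width
20 ms; STD centers 10..100 ms, half-width 10 ms.  A trial may enter several
bins; bins with fewer than 5 trials for a participant are invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequences import Block

__all__ = [
    "MEAN_CENTERS",
    "STD_CENTERS",
    "N_MEAN_RANGE",
    "N_STD_RANGE",
    "PerformanceMap2D",
    "ZMap",
    "compute_history_features",
    "cohort_features",
    "bin_performance_map",
    "zscore_map",
    "stack_group",
]

N_MEAN_RANGE = range(1, 8)
N_STD_RANGE = range(2, 8)

# Sliding-window grids: 10 ms center spacing on the mean axis and 5 ms on the
# STD axis give >= 50% overlap between adjacent +/-20 ms and +/-10 ms windows.
MEAN_CENTERS = np.arange(400.0, 601.0, 10.0)
STD_CENTERS = np.arange(10.0, 101.0, 5.0)
MEAN_HALFWIDTH = 20.0
STD_HALFWIDTH = 10.0
MIN_COUNT = 5


def compute_history_features(block: Block, block_id: int | None = None,
                             subject: str | None = None) -> pd.DataFrame:
    """Local SOA statistics for every target of a block.

    Returns one row per target with ``last_soa_ms``, ``mean_1..mean_7`` and
    ``std_2..std_7`` (sample STD).  ``ddof=1`` throughout; a config switch
    for population STD lives in :func:`cohort_features`.
    """
    return _features_from_soa(
        block.soa_array,
        block.target_indices,
        block.condition.std_soa,
        subject=subject,
        block_id=block_id,
    )


def _features_from_soa(
    soa_by_index: np.ndarray,
    target_indices: np.ndarray,
    condition_std: float,
    subject: str | None = None,
    block_id: int | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    t = np.asarray(target_indices, dtype=int)
    cols: dict = {
        "subject": subject,
        "block": block_id,
        "trial_index": t,
        "condition_std_ms": condition_std,
        "last_soa_ms": soa_by_index[t] if len(t) else np.array([]),
    }
    n_max = max(N_MEAN_RANGE)
    # windows[k, j] = SOA of trial t_k - j: the j-th interval back from target k
    windows = soa_by_index[t[:, None] - np.arange(n_max)[None, :]] if len(t) else None
    if windows is not None:
        assert not np.isnan(windows).any(), "SOA window reaches trial 1"
    for n in N_MEAN_RANGE:
        w = windows[:, :n] if windows is not None else np.empty((0, n))
        cols[f"mean_{n}"] = w.mean(axis=1)
        if n in N_STD_RANGE:
            cols[f"std_{n}"] = w.std(axis=1, ddof=ddof)
    frame = pd.DataFrame(cols)
    if not frame.empty:
        assert np.allclose(frame["mean_1"], frame["last_soa_ms"])
    return frame


def cohort_features(trials: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """History features for every target in a long-format trial table.

    ``trials`` must carry the standard trials-CSV columns; ``correct`` and
    ``rt_ms`` columns, if present, are joined onto the feature rows.
    """
    out = []
    for (subject, block), grp in trials.groupby(["subject", "block"], sort=True):
        grp = grp.sort_values("trial_index")
        n = int(grp["trial_index"].max())
        soa = np.full(n + 1, np.nan)
        soa[grp["trial_index"].to_numpy()] = grp["soa_ms"].to_numpy()
        tidx = grp.loc[grp["is_target"] == 1, "trial_index"].to_numpy()
        feats = _features_from_soa(
            soa,
            tidx,
            float(grp["condition_std_ms"].iloc[0]),
            subject=subject,
            block_id=block,
            ddof=ddof,
        )
        extra = [c for c in ("correct", "rt_ms", "is_deviant") if c in grp.columns]
        if extra and not feats.empty:
            resp = grp.loc[grp["is_target"] == 1, ["trial_index", *extra]]
            feats = feats.merge(resp, on="trial_index", how="left")
        out.append(feats)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


@dataclass
class PerformanceMap2D:
    """Per-participant binned map: counts, mean accuracy and mean RT per
    (local mean, local STD) window."""

    mean_centers: np.ndarray
    std_centers: np.ndarray
    count: np.ndarray  # (n_mean, n_std)
    acc: np.ndarray
    rt: np.ndarray
    valid: np.ndarray  # bool


@dataclass
class ZMap:
    mean_centers: np.ndarray
    std_centers: np.ndarray
    z: np.ndarray
    valid: np.ndarray


def bin_performance_map(
    features: pd.DataFrame,
    n_mean: int,
    n_std: int,
    mean_centers: np.ndarray = MEAN_CENTERS,
    std_centers: np.ndarray = STD_CENTERS,
    mean_halfwidth: float = MEAN_HALFWIDTH,
    std_halfwidth: float = STD_HALFWIDTH,
    min_count: int = MIN_COUNT,
) -> PerformanceMap2D:
    """Bin one participant's targets into overlapping 2-D windows.

    A target with local mean m and local STD s enters bin (M, S) when
    ``|m - M| <= mean_halfwidth`` and ``|s - S| <= std_halfwidth``
    (inclusive boundaries; ties enter both adjacent bins).  ``features`` may
    pool several N by concatenating rows before calling.
    """
    if not (1 <= n_mean <= 7) or not (2 <= n_std <= 7):
        raise ValueError("n_mean must be in 1..7 and n_std in 2..7")
    mean_centers = np.asarray(mean_centers, dtype=float)
    std_centers = np.asarray(std_centers, dtype=float)
    shape = (len(mean_centers), len(std_centers))
    if features.empty:
        zero = np.zeros(shape)
        return PerformanceMap2D(
            mean_centers, std_centers, zero, np.full(shape, np.nan),
            np.full(shape, np.nan), np.zeros(shape, dtype=bool),
        )
    m = features[f"mean_{n_mean}"].to_numpy(dtype=float)
    s = features[f"std_{n_std}"].to_numpy(dtype=float)
    correct = features["correct"].to_numpy(dtype=float)
    rt = features["rt_ms"].to_numpy(dtype=float)
    in_m = np.abs(m[None, :] - mean_centers[:, None]) <= mean_halfwidth
    in_s = np.abs(s[None, :] - std_centers[:, None]) <= std_halfwidth
    in_mf = in_m.astype(float)
    in_sf = in_s.astype(float)
    count = in_mf @ in_sf.T
    acc_sum = in_mf @ (in_sf * correct[None, :]).T
    rt_sum = in_mf @ (in_sf * rt[None, :]).T
    valid = count >= min_count
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(valid, acc_sum / count, np.nan)
        rt_mean = np.where(valid, rt_sum / count, np.nan)
    return PerformanceMap2D(mean_centers, std_centers, count, acc, rt_mean, valid)


def zscore_map(pmap: PerformanceMap2D, field: str = "acc") -> ZMap:
    """Z-score a participant's map over its valid bins (mean 0, sample SD 1).

    Fewer than 2 valid bins, or zero variance across them, yields an
    all-invalid map with a warning.
    """
    if field not in ("acc", "rt"):
        raise ValueError("field must be 'acc' or 'rt'")
    values = getattr(pmap, field)
    valid = pmap.valid.copy()
    z = np.full(values.shape, np.nan)
    vals = values[valid]
    if valid.sum() < 2:
        warnings.warn("fewer than 2 valid bins; z-map is all-invalid")
        return ZMap(pmap.mean_centers, pmap.std_centers, z, np.zeros_like(valid))
    sd = np.std(vals, ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(vals).max())):
        warnings.warn("zero variance across valid bins; z-map is all-invalid")
        return ZMap(pmap.mean_centers, pmap.std_centers, z, np.zeros_like(valid))
    z[valid] = (vals - vals.mean()) / sd
    return ZMap(pmap.mean_centers, pmap.std_centers, z, valid)


def stack_group(zmaps: list[ZMap]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-participant z-maps; a bin survives only if valid for all.

    Returns the (participants, n_mean, n_std) array (NaN outside the joint
    mask) and the joint boolean mask.
    """
    if not zmaps:
        raise ValueError("no z-maps to stack")
    mask = np.logical_and.reduce([m.valid for m in zmaps])
    if not mask.any():
        raise ValueError("no bin is valid for every participant")
    data = np.stack([m.z for m in zmaps])
    data[:, ~mask] = np.nan
    return data, mask
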