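"""Expression-pattern association for candidate genes.

Two screens single out a silk-synthesis gene among the region candidates:
(a) temporal — does 5th-instar silk-gland expression track the gland's
daily volume increments, and (b) across strains — is expression higher in
strains spinning heavier cocoon shells?  Sample sizes are small (a dozen
strains, under ten days), so inference is by seeded permutation tests with
the classical correlation / t statistics reported alongside.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def growth_increments(volumes: pd.Series) -> pd.DataFrame:
    """Daily absolute increments and relative growth ratios of gland volume.

    ``volumes`` is indexed by day (ordered).  For each day after the first:
    increment = V_t - V_{t-1}; ratio = increment / V_{t-1} (NaN and flagged
    when the previous volume is 0).  Shrinkage (negative increments) is
    allowed.
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 days of volumes")
    v = volumes.astype(float)
    inc = v.diff().iloc[1:]
    prev = v.shift(1).iloc[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(prev > 0, inc / prev, np.nan)
    out = pd.DataFrame({"day": v.index[1:], "increment": inc.to_numpy(), "ratio": ratio})
    n_undef = int(np.isnan(ratio).sum())
    if n_undef:
        logger.warning("%d growth ratios undefined (zero previous volume)", n_undef)
    return out


def _permutation_p(x: np.ndarray, y: np.ndarray, statistic, n_permutations: int, rng) -> float:
    """Two-sided permutation p for a statistic of paired vectors (y shuffled)."""
    observed = statistic(x, y)
    count = 1  # include the observed arrangement
    for _ in range(n_permutations):
        perm = statistic(x, rng.permutation(y))
        if abs(perm) >= abs(observed) - 1e-12:
            count += 1
    return count / (n_permutations + 1)


def _pearson(x, y):
    return stats.pearsonr(x, y).statistic


def _spearman(x, y):
    return stats.spearmanr(x, y).statistic


def temporal_association(
    expression: pd.Series,
    increments: pd.Series,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Correlate a gene's daily expression with gland-volume increments.

    Both series are aligned on their index (day labels).  Reports Pearson and
    Spearman correlations with seeded permutation p-values, plus the
    correlation against the negated increments, which captures genes whose
    expression falls as gland growth accelerates.
    """
    joined = pd.concat(
        [expression.rename("expr"), increments.rename("inc")], axis=1, join="inner"
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired points")
    x = joined["expr"].to_numpy(float)
    y = joined["inc"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return {"n": len(joined), "pearson_r": np.nan, "spearman_rho": np.nan,
                "pearson_p": np.nan, "spearman_p": np.nan, "defined": False}
    rng = np.random.default_rng(seed)
    report = {
        "n": len(joined),
        "pearson_r": _pearson(x, y),
        "spearman_rho": _spearman(x, y),
        "pearson_p": _permutation_p(x, y, _pearson, n_permutations, rng),
        "spearman_p": _permutation_p(x, y, _spearman, n_permutations,
                                     np.random.default_rng(seed + 1)),
        "defined": True,
    }
    report["pearson_r_vs_negative"] = -report["pearson_r"]
    return report


def _welch_t(x_groups, y):
    """Welch t statistic where y is a boolean high-group mask over x_groups."""
    hi = x_groups[y]
    lo = x_groups[~y]
    return stats.ttest_ind(hi, lo, equal_var=False).statistic


def csw_association(
    expression: pd.Series,
    csw: pd.Series,
    grouping: str = "correlate",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Association between strain expression and cocoon shell weight.

    ``correlate`` reports the Spearman correlation of expression with CSW and
    a seeded permutation p.  ``split`` partitions strains at the CSW median
    into high/low groups and permutation-tests the difference in mean
    expression with a Welch t statistic.  All-equal CSW makes the split
    undefined; it falls back to correlate with a warning.
    """
    joined = pd.concat(
        [expression.rename("expr"), csw.rename("csw")], axis=1, join="inner"
    ).dropna()
    if len(joined) < 4:
        raise ValueError("need at least 4 strains present in both tables")
    x = joined["expr"].to_numpy(float)
    w = joined["csw"].to_numpy(float)
    rng = np.random.default_rng(seed)
    if grouping == "split" and np.ptp(w) == 0:
        logger.warning("all CSW equal; median split undefined, using correlate")
        grouping = "correlate"
    if grouping == "correlate":
        if np.std(x) == 0 or np.std(w) == 0:
            return {"mode": "correlate", "n": len(joined),
                    "spearman_rho": np.nan, "p": 1.0, "defined": np.std(w) > 0}
        rho = _spearman(x, w)
        p = _permutation_p(w, x, lambda a, b: _spearman(b, a), n_permutations, rng)
        return {"mode": "correlate", "n": len(joined), "spearman_rho": rho,
                "p": p, "defined": True}
    if grouping == "split":
        high = w > np.median(w)
        if high.sum() == 0 or (~high).sum() == 0:
            high = w >= np.median(w)
        diff = float(x[high].mean() - x[~high].mean())
        if np.std(x) == 0:
            return {"mode": "split", "n": len(joined), "mean_difference": 0.0,
                    "t": np.nan, "p": 1.0, "defined": True}
        observed = _welch_t(x, high)
        count = 1
        for _ in range(n_permutations):
            perm = _welch_t(x, rng.permutation(high))
            if abs(perm) >= abs(observed) - 1e-12:
                count += 1
        return {
            "mode": "split", "n": len(joined), "mean_difference": diff,
            "t": float(observed), "p": count / (n_permutations + 1),
            "n_high": int(high.sum()), "n_low": int((~high).sum()), "defined": True,
        }
    raise ValueError(f"grouping must be 'correlate' or 'split', got {grouping!r}")
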