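"""SNP-index bulked-segregant scan.

Two sequencing pools are built from the phenotypic extremes of a BC1
mapping population (L-pool = low phenotype, H-pool = high phenotype).
For every polymorphic marker the read depth is split into an "aa"
(homozygous recessive) channel and an "ab" (heterozygous) channel per
pool.  The SNP-index contrasts the two pools within each channel:

    SNP_index(aa) = Maa / (Paa + Maa)
    SNP_index(ab) = Mab / (Pab + Mab)
    delta         = SNP_index(aa) - SNP_index(ab)

where M* are L-pool depths and P* are H-pool depths.  A marker linked to
the trait distorts the pooled allele representation and pushes delta away
from the genome-wide background; delta is standardised into a Z score,
converted to a normal-tail p-value and adjusted for multiple testing.
Markers below the FDR threshold are called linked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

logger = logging.getLogger(__name__)

DEPTH_COLUMNS = ["Maa", "Mab", "Paa", "Pab"]

#: Wording used in scan reports when the printed-method name ("Bonferroni")
#: and the method actually consistent with the published calls (BH) differ.
METHOD_DISCREPANCY_NOTE = (
    "Note: the source protocol names Bonferroni for the FDR correction, but "
    "its published linked-marker calls are reproducible only with "
    "Benjamini-Hochberg step-up; this scan used method={method!r}."
)


def snp_index(
    maa: np.ndarray, mab: np.ndarray, paa: np.ndarray, pab: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker SNP-index for both genotype channels and their difference.

    Markers with a zero denominator in either channel get NaN in every
    output and are meant to be excluded from the scan by the caller.

    Returns
    -------
    (index_aa, index_ab, delta) : float arrays aligned with the input.
    """
    maa = np.asarray(maa, dtype=float)
    mab = np.asarray(mab, dtype=float)
    paa = np.asarray(paa, dtype=float)
    pab = np.asarray(pab, dtype=float)
    denom_aa = maa + paa
    denom_ab = mab + pab
    with np.errstate(invalid="ignore", divide="ignore"):
        idx_aa = np.where(denom_aa > 0, maa / denom_aa, np.nan)
        idx_ab = np.where(denom_ab > 0, mab / denom_ab, np.nan)
    defined = (denom_aa > 0) & (denom_ab > 0)
    idx_aa = np.where(defined, idx_aa, np.nan)
    idx_ab = np.where(defined, idx_ab, np.nan)
    return idx_aa, idx_ab, idx_aa - idx_ab


def z_scores(
    deltas: np.ndarray, scale: str = "se"
) -> tuple[np.ndarray, float, float, int]:
    """Standardise delta values against the genome-wide background.

    Z = (X - mu0) / (S / sqrt(n)) with X a marker's delta, mu0 the mean of
    all deltas, S their sample standard deviation and n the number of
    tested markers.  ``scale="se"`` is that verbatim form (the published
    arithmetic); ``scale="sd"`` divides by S alone, giving a classically
    calibrated z score suitable for simulation-based inference.

    Returns ``(z, mu0, S, n)``.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim != 1:
        raise ValueError("deltas must be one-dimensional")
    n = deltas.size
    if n < 2:
        raise ValueError(f"need at least 2 markers to standardise, got {n}")
    mu0 = float(np.mean(deltas))
    s = float(np.std(deltas, ddof=1))
    if s == 0.0:
        raise ValueError("all delta values are identical (S = 0); Z undefined")
    if scale == "se":
        denom = s / np.sqrt(n)
    elif scale == "sd":
        denom = s
    else:
        raise ValueError(f"scale must be 'se' or 'sd', got {scale!r}")
    return (deltas - mu0) / denom, mu0, s, n


def p_from_z(z: np.ndarray, sided: str = "one") -> np.ndarray:
    """Normal-tail p-value of a Z score.

    one-sided: p = 1 - Phi(z).  two-sided: p = 2 * (1 - Phi(z)), computed on
    the signed z — deliberately not folded through |z| and not capped at 1,
    so a negative z yields p > 1.  This is the convention of the published
    confirmation table, whose negative-z rows print p-values above 1.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite values")
    tail = ndtr(-z)  # 1 - Phi(z), accurate deep into the tail
    if sided == "one":
        return tail if tail.ndim else float(tail)
    if sided == "two":
        p = 2.0 * tail
        return p if p.ndim else float(p)
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def adjust_fdr(
    p: np.ndarray, method: str = "bh", n_tests: int | None = None
) -> np.ndarray:
    """Multiple-testing adjustment supporting a test count beyond the list.

    ``n_tests`` may exceed ``len(p)`` when only the smallest p-values of a
    genome scan are supplied (the remaining markers are known only to rank
    above them).  Bonferroni returns p * n_tests uncapped; BH returns the
    step-up adjusted value q_(i) = min_{j >= i} p_(j) * n_tests / j over
    ascending ranks, mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("p-values must be non-negative")
    m = p.size
    if n_tests is None:
        n_tests = m
    if n_tests < m:
        raise ValueError(f"n_tests ({n_tests}) smaller than number of p-values ({m})")
    if method == "bonferroni":
        return p * n_tests
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * n_tests / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(m)
        q[order] = q_sorted
        return q
    raise ValueError(f"method must be 'bh' or 'bonferroni', got {method!r}")


def filter_polymorphic(depths: pd.DataFrame, min_coverage: int = 5) -> pd.DataFrame:
    """Keep markers whose total depth over all four channels exceeds min_coverage.

    The inequality is strict ("more than"), so a marker summing exactly to
    min_coverage is dropped.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    total = depths[DEPTH_COLUMNS].sum(axis=1)
    kept = depths.loc[total > min_coverage].reset_index(drop=True)
    logger.info(
        "coverage filter (> %dx): %d of %d markers retained",
        min_coverage, len(kept), len(depths),
    )
    return kept


def call_linked(scan: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Flag markers with adjusted value strictly below the threshold."""
    scan = scan.copy()
    scan["linked"] = scan["fdr"] < fdr_threshold
    n_linked = int(scan["linked"].sum())
    tally = scan.loc[scan["linked"], "chrom"].value_counts().to_dict() if n_linked else {}
    logger.info("linked markers at FDR < %g: %d %s", fdr_threshold, n_linked, tally)
    return scan


@dataclass
class ScanResult:
    """Per-marker scan table plus the scan-level standardisation constants."""

    table: pd.DataFrame
    mu0: float
    s: float
    n: int
    fdr_threshold: float
    method: str
    sided: str
    scale: str
    n_excluded: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def linked(self) -> pd.DataFrame:
        return self.table.loc[self.table["linked"]]

    def summary(self) -> dict:
        return {
            "n_markers": self.n,
            "n_excluded_zero_depth": self.n_excluded,
            "mu0": self.mu0,
            "S": self.s,
            "n_linked": int(self.table["linked"].sum()),
            "fdr_threshold": self.fdr_threshold,
            "method": self.method,
            "sided": self.sided,
            "scale": self.scale,
            "notes": self.notes,
        }


def scan_depths(
    depths: pd.DataFrame,
    min_coverage: int = 5,
    fdr_threshold: float = 0.05,
    method: str = "bh",
    sided: str = "one",
    scale: str = "se",
    n_tests: int | None = None,
) -> ScanResult:
    """Run the full marker scan on a pooled depth table.

    Expects columns marker_id, chrom, pos, Maa, Mab, Paa, Pab.  Markers
    failing the coverage filter or with an undefined index (zero depth in a
    channel) are excluded before standardisation; n is the number of markers
    actually tested unless ``n_tests`` overrides it for the adjustment.
    """
    filtered = filter_polymorphic(depths, min_coverage)
    idx_aa, idx_ab, delta = snp_index(
        filtered["Maa"], filtered["Mab"], filtered["Paa"], filtered["Pab"]
    )
    defined = np.isfinite(delta)
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info("excluded %d markers with a zero-depth channel", n_excluded)
    tested = filtered.loc[defined].reset_index(drop=True)
    tested["snp_index_aa"] = idx_aa[defined]
    tested["snp_index_ab"] = idx_ab[defined]
    tested["delta"] = delta[defined]
    z, mu0, s, n = z_scores(tested["delta"].to_numpy(), scale=scale)
    tested["z"] = z
    tested["p"] = p_from_z(z, sided=sided)
    tested["fdr"] = adjust_fdr(tested["p"].to_numpy(), method=method, n_tests=n_tests)
    tested = call_linked(tested, fdr_threshold)
    notes = [METHOD_DISCREPANCY_NOTE.format(method=method)]
    return ScanResult(
        table=tested, mu0=mu0, s=s, n=n, fdr_threshold=fdr_threshold,
        method=method, sided=sided, scale=scale, n_excluded=n_excluded,
        notes=notes,
    )
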