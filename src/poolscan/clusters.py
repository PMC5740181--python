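"""Genomic clustering of differentially expressed genes.

Genes acting on the same physiology often sit in adjoining genomic
regions.  Given one position per DEG (midpoint of the gene span), the
analysis compares adjacent-gene intervals per chromosome against the
uniform expectation genome_size / n_genes, summarises the interval/expected
ratio distribution, and calls a cluster wherever three or more consecutive
genes are separated by intervals below a threshold — either an absolute gap
(30 kb, about the genome-wide average gene interval) or a fraction (10%) of
the expected interval.  A permutation test against uniform re-placement
gives an empirical p for the observed clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ClusterCall:
    """A maximal run of >=3 consecutive genes with all gaps under threshold."""

    chrom: str
    gene_ids: list[str]
    start: int
    end: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def span(self) -> int:
        return self.end - self.start


def _sorted_positions(degs: pd.DataFrame) -> pd.DataFrame:
    return degs.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def adjacent_intervals(degs: pd.DataFrame) -> pd.DataFrame:
    """Successive position differences per chromosome, never across chromosomes.

    ``degs`` needs gene_id, chrom, pos.  Duplicate positions yield interval 0.
    """
    degs = _sorted_positions(degs)
    rows = []
    for chrom, group in degs.groupby("chrom", sort=True):
        pos = group["pos"].to_numpy()
        ids = group["gene_id"].to_numpy()
        for i in range(1, len(pos)):
            rows.append((chrom, ids[i - 1], ids[i], int(pos[i] - pos[i - 1])))
    out = pd.DataFrame(rows, columns=["chrom", "gene_left", "gene_right", "interval"])
    n_zero = int((out["interval"] == 0).sum()) if len(out) else 0
    if n_zero:
        logger.info("%d zero-length intervals (duplicate positions)", n_zero)
    return out


def expected_interval(n_genes: int, genome_size: int) -> float:
    """Uniform expectation: total genome size divided by the gene count."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return genome_size / n_genes


def ratio_summary(
    intervals: np.ndarray,
    expected: float,
    bins: np.ndarray | None = None,
) -> dict:
    """Distribution of interval/expected ratios.

    Reports the fraction of gene pairs strictly below the expectation and
    strictly below one tenth of it, plus a histogram over ``bins`` (default
    0, 0.1, ..., 2.0 with an overflow bin).
    """
    if expected <= 0:
        raise ValueError("expected interval must be positive")
    intervals = np.asarray(intervals, dtype=float)
    ratios = intervals / expected
    if bins is None:
        bins = np.concatenate([np.arange(0, 2.01, 0.1), [np.inf]])
    hist, edges = np.histogram(ratios, bins=bins)
    return {
        "n_pairs": int(ratios.size),
        "fraction_below_1": float(np.mean(ratios < 1.0)) if ratios.size else np.nan,
        "fraction_below_0.1": float(np.mean(ratios < 0.1)) if ratios.size else np.nan,
        "histogram": hist.tolist(),
        "bin_edges": [float(e) for e in edges],
    }


def call_clusters(
    degs: pd.DataFrame,
    threshold_mode: str = "absolute",
    threshold_value: float = 30_000,
    genome_size: int | None = None,
) -> list[ClusterCall]:
    """Maximal runs of >=3 consecutive genes with every gap strictly below threshold.

    ``absolute`` mode uses ``threshold_value`` in bp; ``fraction`` mode uses
    ``threshold_value`` times the expected interval (requires genome_size).
    An interval exactly equal to the threshold breaks the run.  Output is
    independent of the input row order (positions are sorted internally).
    """
    if threshold_value <= 0:
        raise ValueError("threshold_value must be positive")
    if threshold_mode == "absolute":
        cutoff = float(threshold_value)
    elif threshold_mode == "fraction":
        if genome_size is None:
            raise ValueError("fraction mode needs genome_size")
        cutoff = threshold_value * expected_interval(len(degs), genome_size)
    else:
        raise ValueError(f"threshold_mode must be 'absolute' or 'fraction', got {threshold_mode!r}")

    degs = _sorted_positions(degs)
    calls: list[ClusterCall] = []
    for chrom, group in degs.groupby("chrom", sort=True):
        pos = group["pos"].to_numpy()
        ids = group["gene_id"].to_numpy()
        run_start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] >= cutoff:
                if i - run_start >= 3:
                    calls.append(
                        ClusterCall(
                            chrom=chrom,
                            gene_ids=list(ids[run_start:i]),
                            start=int(pos[run_start]),
                            end=int(pos[i - 1]),
                        )
                    )
                run_start = i
    return calls


def cluster_size_histogram(calls: list[ClusterCall]) -> dict[int, int]:
    """Count of clusters by member-gene number."""
    hist: dict[int, int] = {}
    for c in calls:
        hist[c.n_genes] = hist.get(c.n_genes, 0) + 1
    return dict(sorted(hist.items()))


def clusters_to_frame(calls: list[ClusterCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.n_genes, c.span, ";".join(c.gene_ids))
            for c in calls
        ],
        columns=["chrom", "start", "end", "n_genes", "span", "gene_ids"],
    )


def cluster_summary(
    degs: pd.DataFrame,
    genome_size: int,
    absolute_bp: float = 30_000,
    fraction: float = 0.1,
) -> dict:
    """Side-by-side report of both threshold modes plus the ratio summary.

    The two published threshold conventions (30 kb absolute; 10% of the
    expected interval) need not agree; the report flags when they differ.
    """
    intervals = adjacent_intervals(degs)["interval"].to_numpy()
    expected = expected_interval(len(degs), genome_size)
    abs_calls = call_clusters(degs, "absolute", absolute_bp)
    frac_calls = call_clusters(degs, "fraction", fraction, genome_size=genome_size)
    return {
        "n_genes": len(degs),
        "expected_interval": expected,
        "ratios": ratio_summary(intervals, expected),
        "n_clusters_absolute": len(abs_calls),
        "n_clusters_fraction": len(frac_calls),
        "size_histogram_absolute": cluster_size_histogram(abs_calls),
        "size_histogram_fraction": cluster_size_histogram(frac_calls),
        "modes_disagree": len(abs_calls) != len(frac_calls),
    }


def cluster_null_test(
    degs: pd.DataFrame,
    chrom_sizes: dict[str, int],
    threshold_mode: str = "absolute",
    threshold_value: float = 30_000,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Empirical p of the observed clustering under uniform re-placement.

    Keeps the per-chromosome gene counts fixed and re-draws positions
    uniformly on each chromosome ``n_permutations`` times; p is the fraction
    of permutations (plus the observed arrangement) reaching at least the
    observed cluster count, and separately at least the observed fraction of
    intervals below the expectation.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    genome_size = int(sum(chrom_sizes.values()))
    expected = expected_interval(len(degs), genome_size)

    def stats_for(frame: pd.DataFrame) -> tuple[int, float]:
        calls = call_clusters(frame, threshold_mode, threshold_value,
                              genome_size=genome_size)
        iv = adjacent_intervals(frame)["interval"].to_numpy()
        frac = float(np.mean(iv < expected)) if iv.size else 0.0
        return len(calls), frac

    observed_clusters, observed_frac = stats_for(degs)
    rng = np.random.default_rng(seed)
    counts = degs.groupby("chrom")["pos"].size()
    ge_clusters = 1
    ge_frac = 1
    for _ in range(n_permutations):
        frames = []
        for chrom, k in counts.items():
            pos = np.sort(rng.integers(1, chrom_sizes[chrom] + 1, size=k))
            frames.append(pd.DataFrame(
                {"gene_id": [f"{chrom}_{i}" for i in range(k)], "chrom": chrom, "pos": pos}
            ))
        null = pd.concat(frames, ignore_index=True)
        nc, nf = stats_for(null)
        if nc >= observed_clusters:
            ge_clusters += 1
        if nf >= observed_frac:
            ge_frac += 1
    return {
        "observed_clusters": observed_clusters,
        "observed_fraction_below_expected": observed_frac,
        "p_clusters": ge_clusters / (n_permutations + 1),
        "p_fraction": ge_frac / (n_permutations + 1),
        "n_permutations": n_permutations,
    }
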