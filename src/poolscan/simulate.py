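"""Synthetic BC1 mapping populations and pooled sequencing.

Generates data with the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without touching an archive.
The emulated design is a silkworm backcross for cocoon shell weight (CSW):
a low-silk inbred crossed to a high-silk stock, F1 males backcrossed to the
low parent, yielding BC1 males that are aa or ab at every locus with equal
probability.  Seven families ("moth areas") of 127-174 males are reared,
the ~10% phenotypic extremes of each family are pooled, and the two pools
are sequenced to ~245x per marker.

Gametes recombine under the Haldane map function; physical coordinates use
the genome's ~300 kb per cM conversion.  Pooled read depths are Poisson
per marker per pool, with reads assigned to the aa/ab channels from the
pool's true allele composition (allele-depth convention by default; a
genotype-dosage convention is selectable) and flipped by a sequencing
error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Physical scale of the genetic map: ~300 kb of sequence per centimorgan.
BP_PER_CM = 300_000

#: Default genome: 28 chromosomes of ~51 cM (~15.4 Mb) each, ~432 Mb total.
DEFAULT_CHROMOSOMES = {f"chr{i:02d}": 51.0 for i in range(1, 29)}

AA, AB = 0, 1  # genotype codes: homozygous low-parent / heterozygous


@dataclass
class CrossDesign:
    """Parameters of the backcross, pooling and sequencing design.

    Defaults are the emulated study's stated design where stated: 7 families
    of 127-174 males, 10% tails per family, 245x mean depth.  Phenotype units
    are grams of cocoon shell; the default QTL effect of 0.10 g is twice the
    residual SD (0.05 g) around a 0.25 g baseline.
    """

    n_families: int = 7
    family_size_range: tuple[int, int] = (127, 174)
    pool_fraction: float = 0.10
    chromosomes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOMES)
    )
    qtl: list[tuple[str, float, float]] = field(default_factory=list)
    baseline_csw: float = 0.25
    phenotype_noise_sd: float = 0.05
    marker_spacing_cm: float = 1.0
    mean_depth: float = 245.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.family_size_range
        if not (0 < lo <= hi):
            raise ValueError("family_size_range must satisfy 0 < lo <= hi")
        if not (0 < self.pool_fraction <= 0.5):
            raise ValueError("pool_fraction must be in (0, 0.5]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.marker_spacing_cm <= 0:
            raise ValueError("marker_spacing_cm must be positive")
        for chrom, pos_cm, _effect in self.qtl:
            if chrom not in self.chromosomes:
                raise ValueError(f"QTL chromosome {chrom!r} not in the simulated map")
            if not (0 <= pos_cm <= self.chromosomes[chrom]):
                raise ValueError(
                    f"QTL position {pos_cm} cM outside chromosome {chrom!r} "
                    f"(0..{self.chromosomes[chrom]} cM)"
                )


@dataclass
class SimulatedPopulation:
    """A simulated BC1 population with its ground truth.

    ``genotypes`` is individuals x markers with 0 = aa, 1 = ab; ``markers``
    lists marker_id, chrom, pos_cm and pos (1-based bp).  QTL genotypes are
    carried separately so a QTL need not coincide with a marker.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    phenotypes: np.ndarray
    family_id: np.ndarray
    qtl_genotypes: np.ndarray
    truth: list[tuple[str, float, float]]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def individuals_frame(self) -> pd.DataFrame:
        """Per-individual table: id, family, phenotype, one column per marker."""
        geno = np.where(self.genotypes == AB, "ab", "aa")
        df = pd.DataFrame(geno, columns=self.markers["marker_id"])
        df.insert(0, "phenotype", self.phenotypes)
        df.insert(0, "family", self.family_id)
        df.insert(0, "individual_id", [f"ind_{i:05d}" for i in range(len(df))])
        return df


def haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-0.02 * np.asarray(d_cm, dtype=float)))


def _chromosome_loci(design: CrossDesign) -> pd.DataFrame:
    """Marker grid plus QTL loci, per chromosome, sorted by position."""
    rows = []
    for chrom, length in design.chromosomes.items():
        grid = np.arange(0.0, length + 1e-9, design.marker_spacing_cm)
        for pos in grid:
            rows.append((chrom, float(pos), False, np.nan))
        for qchrom, qpos, qeff in design.qtl:
            if qchrom == chrom:
                rows.append((chrom, float(qpos), True, qeff))
    loci = pd.DataFrame(rows, columns=["chrom", "pos_cm", "is_qtl", "effect"])
    return loci.sort_values(["chrom", "pos_cm", "is_qtl"], kind="stable").reset_index(
        drop=True
    )


def simulate_bc1(
    design: CrossDesign, rng: np.random.Generator | None = None
) -> SimulatedPopulation:
    """Simulate genotypes and phenotypes of a BC1 mapping population.

    Each individual's F1-derived gamete is generated chromosome by
    chromosome as a two-state Markov chain along the loci: the first locus
    carries either parental allele with probability 1/2 and each inter-locus
    interval recombines with the Haldane probability for its map distance.
    Phenotype = baseline + sum of effects over heterozygous QTLs + Gaussian
    noise.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    sizes = rng.integers(
        design.family_size_range[0], design.family_size_range[1] + 1,
        size=design.n_families,
    )
    n = int(sizes.sum())
    family_id = np.repeat(np.arange(design.n_families), sizes)

    loci = _chromosome_loci(design)
    geno_cols = []
    for chrom, group in loci.groupby("chrom", sort=False):
        pos = group["pos_cm"].to_numpy()
        r = haldane_r(np.diff(pos))
        start = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
        if len(pos) > 1:
            cross = (rng.random((n, len(pos) - 1)) < r).astype(np.int8)
            switches = np.concatenate([start, cross], axis=1).astype(np.int64)
            geno = (np.cumsum(switches, axis=1) % 2).astype(np.int8)
        else:
            geno = start
        geno_cols.append(geno)
    genotypes_all = np.concatenate(geno_cols, axis=1)

    is_qtl = loci["is_qtl"].to_numpy()
    qtl_genotypes = genotypes_all[:, is_qtl]
    marker_geno = genotypes_all[:, ~is_qtl]
    markers = loci.loc[~is_qtl, ["chrom", "pos_cm"]].reset_index(drop=True)
    markers["pos"] = (markers["pos_cm"] * BP_PER_CM).round().astype(int) + 1
    markers.insert(
        0, "marker_id",
        [f"{c}_{p}" for c, p in zip(markers["chrom"], markers["pos"])],
    )

    effects = loci.loc[is_qtl, "effect"].to_numpy()
    phenotypes = (
        design.baseline_csw
        + qtl_genotypes @ effects
        + rng.normal(0.0, design.phenotype_noise_sd, size=n)
    )
    return SimulatedPopulation(
        genotypes=marker_geno,
        markers=markers,
        phenotypes=phenotypes,
        family_id=family_id,
        qtl_genotypes=qtl_genotypes,
        truth=list(design.qtl),
    )


def build_pools(
    pop: SimulatedPopulation, pool_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the per-family low and high phenotypic extremes.

    Within each family individuals are ordered stably by (phenotype, index);
    the bottom and top ``floor(fraction * family size)`` (minimum 1) are
    taken and unioned over families.  With fraction 0.5 the two pools
    partition each even-sized family.
    """
    if not (0 < pool_fraction <= 0.5):
        raise ValueError("pool_fraction must be in (0, 0.5]")
    low, high = [], []
    for fam in np.unique(pop.family_id):
        members = np.flatnonzero(pop.family_id == fam)
        if members.size == 0:
            raise ValueError(f"family {fam} is empty")
        order = members[np.lexsort((members, pop.phenotypes[members]))]
        k = max(1, int(np.floor(pool_fraction * members.size)))
        low.append(order[:k])
        high.append(order[-k:])
    return np.concatenate(low), np.concatenate(high)


def _channel_depths(
    genotypes: np.ndarray,
    mean_depth: float,
    error_rate: float,
    convention: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (aa-channel, ab-channel) depths for one pool at every marker."""
    n_ind, n_markers = genotypes.shape
    n_ab = genotypes.sum(axis=0)
    total = rng.poisson(mean_depth, size=n_markers)
    if convention == "allele":
        # only alleles are observable in a pool: each read carries the
        # low-parent allele with the pool's a-allele frequency
        p_aa = 1.0 - n_ab / (2.0 * n_ind)
        p_aa = p_aa * (1 - error_rate) + (1 - p_aa) * error_rate
        aa = rng.binomial(total, p_aa)
    elif convention == "dosage":
        # reads from heterozygous individuals split half-and-half
        from_ab = rng.binomial(total, n_ab / n_ind)
        aa0 = (total - from_ab) + rng.binomial(from_ab, 0.5)
        aa = rng.binomial(aa0, 1 - error_rate) + rng.binomial(total - aa0, error_rate)
    else:
        raise ValueError(f"convention must be 'allele' or 'dosage', got {convention!r}")
    return aa, total - aa


def pooled_depths(
    pop: SimulatedPopulation,
    low_ids: np.ndarray,
    high_ids: np.ndarray,
    mean_depth: float = 245.0,
    error_rate: float = 0.0,
    convention: str = "allele",
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled sequencing of the two extreme pools: per-marker channel depths.

    Total depth is Poisson around ``mean_depth`` per marker per pool; reads
    land in the aa/ab channels according to the pool's genotype composition
    under the chosen convention and are flipped with ``error_rate``.
    Returns the standard depth table (marker_id, chrom, pos, Maa, Mab, Paa,
    Pab) with M = low pool, P = high pool.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if np.intersect1d(low_ids, high_ids).size:
        raise ValueError("low and high pools overlap")
    if rng is None:
        rng = np.random.default_rng(seed)
    maa, mab = _channel_depths(
        pop.genotypes[low_ids], mean_depth, error_rate, convention, rng
    )
    paa, pab = _channel_depths(
        pop.genotypes[high_ids], mean_depth, error_rate, convention, rng
    )
    out = pop.markers[["marker_id", "chrom", "pos"]].copy()
    out["Maa"], out["Mab"], out["Paa"], out["Pab"] = maa, mab, paa, pab
    return out


def pool_genotype_counts(
    pop: SimulatedPopulation, low_ids: np.ndarray, high_ids: np.ndarray
) -> pd.DataFrame:
    """Individual aa/ab counts per pool at every marker (indel-style genotyping).

    The confirmation stage genotypes pooled individuals one by one; on
    synthetic data the same population truth provides those counts directly.
    """
    out = pop.markers[["marker_id", "chrom", "pos"]].copy()
    for prefix, ids in (("M", low_ids), ("P", high_ids)):
        n_ab = pop.genotypes[ids].sum(axis=0)
        out[f"{prefix}aa"] = len(ids) - n_ab
        out[f"{prefix}ab"] = n_ab
    return out


def simulate_deg_positions(
    n_genes: int,
    genome_size: int,
    mode: str = "uniform",
    clustered_fraction: float = 0.5,
    run_length: int = 5,
    within_run_gap: int = 1000,
    min_gap: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene midpoint positions on a single synthetic chromosome.

    ``uniform`` places all genes uniformly at random; ``clustered`` places
    ``clustered_fraction`` of them in tight runs of ``run_length`` genes
    spaced ``within_run_gap`` apart (far below the expected interval) and
    the rest uniformly.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if genome_size < n_genes * min_gap:
        raise ValueError(
            f"genome_size {genome_size} too small for {n_genes} genes at gap {min_gap}"
        )
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        pos = rng.integers(1, genome_size + 1, size=n_genes)
    elif mode == "clustered":
        n_clustered = int(round(clustered_fraction * n_genes))
        positions = []
        remaining = n_clustered
        while remaining > 0:
            size = min(run_length, remaining)
            span = (size - 1) * within_run_gap
            start = rng.integers(1, genome_size - span + 1)
            positions.extend(start + np.arange(size) * within_run_gap)
            remaining -= size
        positions.extend(rng.integers(1, genome_size + 1, size=n_genes - n_clustered))
        pos = np.asarray(positions)
    else:
        raise ValueError(f"mode must be 'uniform' or 'clustered', got {mode!r}")
    return pd.DataFrame(
        {
            "gene_id": [f"deg_{i:05d}" for i in range(n_genes)],
            "chrom": "genome",
            "pos": pos,
        }
    )


@dataclass
class ExpressionBundle:
    """Synthetic qPCR-style tables for the expression-association stage."""

    strain_expression: pd.Series
    csw: pd.Series
    gland_volume: pd.Series
    temporal_expression: pd.Series


def simulate_expression_tables(
    n_strains: int = 12,
    n_days: int = 8,
    association: str = "none",
    noise_sd: float = 0.15,
    seed: int = 0,
) -> ExpressionBundle:
    """Strain expression vs CSW and daily expression vs gland growth.

    Under ``association="positive"`` strain expression is an increasing noisy
    function of CSW and temporal expression tracks the daily gland-volume
    increments (logistic growth curve); under ``"none"`` expression is
    independent noise.  ``noise_sd`` is in units of the expression signal
    range (the noise-free positive-association expression spans ~1 unit).
    """
    if n_strains < 4:
        raise ValueError("n_strains must be >= 4")
    if n_days < 3:
        raise ValueError("n_days must be >= 3")
    if association not in ("none", "positive"):
        raise ValueError(f"association must be 'none' or 'positive', got {association!r}")
    rng = np.random.default_rng(seed)
    strains = [f"strain_{i:02d}" for i in range(n_strains)]
    csw = pd.Series(np.linspace(0.15, 0.55, n_strains), index=strains, name="csw")

    days = [f"day_{t}" for t in range(n_days)]
    t = np.arange(n_days)
    volume = 100.0 / (1.0 + np.exp(-(t - n_days / 2) / 1.2))
    gland_volume = pd.Series(volume, index=days, name="volume")
    increments = np.diff(volume)

    if association == "positive":
        strain_expr = (
            1.0
            + (csw.to_numpy() - csw.min()) / (csw.max() - csw.min())
            + rng.normal(0.0, noise_sd, n_strains)
        )
        temporal = np.empty(n_days)
        temporal[0] = 0.2
        temporal[1:] = 0.2 + increments / increments.max()
        temporal += rng.normal(0.0, noise_sd, n_days)
    else:
        strain_expr = 1.0 + rng.normal(0.0, max(noise_sd, 0.15), n_strains)
        temporal = 1.0 + rng.normal(0.0, max(noise_sd, 0.15), n_days)
    return ExpressionBundle(
        strain_expression=pd.Series(strain_expr, index=strains, name="expression"),
        csw=csw,
        gland_volume=gland_volume,
        temporal_expression=pd.Series(temporal, index=days, name="expression"),
    )
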