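"""Replicate studies validating the pipeline's statistical behaviour.

These runners exercise the simulator and the scan/confirmation stages under
controlled truths: type-I error of the whole pipeline on zero-effect
populations, recovery of a planted QTL, and the perfect-linkage limit of
the pooled delta statistic.  They are used both by the test suite and by
the reproduction script.

Replicates run at the full study scale: the default 28-chromosome map at
1 cM marker spacing, 7 families of 127-174 males, 10% tails and 245x
depth.  The genome size is not a free parameter here — the scan's Z is
standardised against the genome-wide delta distribution, so the fraction
of markers in linkage with a planted QTL (a few percent on a ~1400 cM
map) is part of what is being validated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bsa_scan, confirm, simulate

STUDY_CHROMOSOMES = dict(simulate.DEFAULT_CHROMOSOMES)


def _study_design(seed: int, qtl: list[tuple[str, float, float]]) -> simulate.CrossDesign:
    return simulate.CrossDesign(
        chromosomes=dict(STUDY_CHROMOSOMES),
        qtl=qtl,
        seed=seed,
    )


def run_replicate(
    seed: int,
    qtl: list[tuple[str, float, float]],
    fdr_threshold: float = 0.05,
) -> dict:
    """One simulate -> pool -> sequence -> scan -> confirm replicate.

    The scan uses the classically calibrated z (``scale="sd"``), one-sided
    p and BH calling; confirmation standardises indel (genotype-count)
    deltas against the non-called markers' null background.  Returns marker
    positions of calls and confirmation counts plus the max-|z| marker.
    """
    design = _study_design(seed, qtl)
    rng = np.random.default_rng(seed)
    pop = simulate.simulate_bc1(design, rng=rng)
    low, high = simulate.build_pools(pop, design.pool_fraction)
    depths = simulate.pooled_depths(
        pop, low, high, mean_depth=design.mean_depth,
        error_rate=design.error_rate, rng=rng,
    )
    scan = bsa_scan.scan_depths(
        depths, scale="sd", sided="one", method="bh", fdr_threshold=fdr_threshold
    )
    top = scan.table.loc[scan.table["z"].abs().idxmax()]
    marker_pos_cm = pop.markers.set_index("marker_id")["pos_cm"]

    linked = scan.linked
    n_confirmed = 0
    if not linked.empty:
        all_counts = simulate.pool_genotype_counts(pop, low, high)
        is_linked = all_counts["marker_id"].isin(linked["marker_id"])
        counts = all_counts.loc[is_linked].copy()
        counts["indel_id"] = counts["marker_id"] + "_gt"
        counts["linked_marker_id"] = counts["marker_id"]
        null_counts = all_counts.loc[~is_linked]
        _, _, background = bsa_scan.snp_index(
            null_counts["Maa"], null_counts["Mab"],
            null_counts["Paa"], null_counts["Pab"],
        )
        confirmed = confirm.confirm_markers(
            linked, counts.drop(columns=["marker_id"]),
            scale="sd", background_deltas=background,
        )
        n_confirmed = int((confirmed["verdict"] == "positive").sum())
    return {
        "n_individuals": pop.n_individuals,
        "n_markers": scan.n,
        "n_linked": int(len(linked)),
        "n_confirmed": n_confirmed,
        "top_marker_chrom": top["chrom"],
        "top_marker_pos_cm": float(marker_pos_cm[top["marker_id"]]),
    }


def type1_study(n_replicates: int = 100, seed: int = 0) -> dict:
    """Zero-effect replicates: how often does the pipeline confirm anything?

    A sound pipeline confirms no marker on almost every null replicate;
    the scan's BH calling holds the family-wise false-call rate near the
    threshold and the confirmation stage removes depth-noise survivors.
    """
    base = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    zero_confirmed = 0
    zero_linked = 0
    for s in base:
        rep = run_replicate(int(s), qtl=[])
        zero_confirmed += rep["n_confirmed"] == 0
        zero_linked += rep["n_linked"] == 0
    return {
        "n_replicates": n_replicates,
        "fraction_zero_confirmed": zero_confirmed / n_replicates,
        "fraction_zero_linked": zero_linked / n_replicates,
    }


def recovery_study(
    n_replicates: int = 50,
    seed: int = 0,
    effect: float = 0.10,
    qtl_chrom: str = "chr11",
    qtl_pos_cm: float = 25.0,
    tolerance_cm: float = 5.0,
) -> dict:
    """Planted-QTL replicates: does the max-|Z| marker land near the truth?

    The default effect (0.10 g against a 0.05 g residual SD) is two
    phenotype SDs, the regime in which extreme-pool sequencing at 245x is
    expected to localise the locus to a few cM.
    """
    base = np.random.SeedSequence(seed + 1).generate_state(n_replicates) % (2**31)
    hits = 0
    confirmed_true = 0
    for s in base:
        rep = run_replicate(int(s), qtl=[(qtl_chrom, qtl_pos_cm, effect)])
        on_target = (
            rep["top_marker_chrom"] == qtl_chrom
            and abs(rep["top_marker_pos_cm"] - qtl_pos_cm) <= tolerance_cm
        )
        hits += on_target
        confirmed_true += rep["n_confirmed"] > 0
    return {
        "n_replicates": n_replicates,
        "fraction_within_tolerance": hits / n_replicates,
        "fraction_any_confirmed": confirmed_true / n_replicates,
        "tolerance_cm": tolerance_cm,
    }


def perfect_linkage_delta(
    n_markers: int = 2000,
    pool_size: int = 100,
    mean_depth: float = 245.0,
    seed: int = 0,
) -> float:
    """Mean pooled delta at a fully linked marker under perfect selection.

    The low pool is entirely aa and the high pool entirely ab, so under the
    allele-depth convention the low pool emits only a-alleles while the
    high pool splits its reads evenly: SNP_index(aa) -> D/(D + D/2) = 2/3
    and SNP_index(ab) -> 0, giving delta -> 2/3.  Simulated over many
    markers to average out depth sampling.
    """
    genotypes = np.concatenate(
        [
            np.zeros((pool_size, n_markers), dtype=np.int8),
            np.ones((pool_size, n_markers), dtype=np.int8),
        ]
    )
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n_markers)],
            "chrom": "chr1",
            "pos_cm": np.arange(n_markers, dtype=float),
            "pos": np.arange(1, n_markers + 1),
        }
    )
    pop = simulate.SimulatedPopulation(
        genotypes=genotypes,
        markers=markers,
        phenotypes=np.concatenate(
            [np.zeros(pool_size), np.ones(pool_size)]
        ),
        family_id=np.zeros(2 * pool_size, dtype=int),
        qtl_genotypes=np.empty((2 * pool_size, 0)),
        truth=[],
    )
    depths = simulate.pooled_depths(
        pop,
        low_ids=np.arange(pool_size),
        high_ids=np.arange(pool_size, 2 * pool_size),
        mean_depth=mean_depth,
        error_rate=0.0,
        seed=seed,
    )
    _, _, delta = bsa_scan.snp_index(
        depths["Maa"], depths["Mab"], depths["Paa"], depths["Pab"]
    )
    return float(np.nanmean(delta))
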