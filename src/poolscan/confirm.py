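"""Confirmation of putative linked markers by individual indel genotyping.

The pooled scan can be distorted by unequal representation of individuals in
a pool, so each putative marker is re-tested on hard genotype counts: a
nearby indel is genotyped one individual at a time in the same pooled
animals, and the index / Z / p machinery is re-applied with individual
counts in place of read depths.  A marker is kept only when the indel's
significance beats its own pooled significance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .bsa_scan import p_from_z, snp_index, z_scores

logger = logging.getLogger(__name__)


def find_flanking_indels(
    marker_chrom: str,
    marker_pos: int,
    indel_catalog: pd.DataFrame,
    window_bp: int = 30_000,
) -> pd.DataFrame:
    """Indels within a window centered on a marker, nearest first.

    The window spans ``[pos - window_bp/2, pos + window_bp/2]`` inclusive on
    the marker's chromosome (default 30 kb, i.e. +/-15 kb).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    half = window_bp / 2
    same = indel_catalog["chrom"] == marker_chrom
    dist = (indel_catalog["pos"] - marker_pos).abs()
    hits = indel_catalog.loc[same & (dist <= half)].copy()
    hits["distance"] = (hits["pos"] - marker_pos).abs()
    hits = hits.sort_values(["distance", "pos"], kind="stable").reset_index(drop=True)
    if hits.empty:
        logger.warning(
            "no indel within %d bp of %s:%d", window_bp, marker_chrom, marker_pos
        )
    return hits


def indel_index_test(
    counts: pd.DataFrame,
    scale: str = "se",
    background_deltas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Index / Z / two-sided p on individual genotype counts.

    ``counts`` has the same four channels as a pooled depth table (Maa, Mab,
    Paa, Pab) but holds counts of aa/ab individuals per pool.  By default
    the Z standardisation (mu0, S, n) runs over the supplied indel set; a
    ``background_deltas`` array substitutes an external null background —
    appropriate when every supplied indel sits at a putative QTL, so the
    set itself carries the signal being tested.  p is two-sided and
    uncapped (negative Z gives p > 1), matching the published convention.
    """
    idx_aa, idx_ab, delta = snp_index(
        counts["Maa"], counts["Mab"], counts["Paa"], counts["Pab"]
    )
    defined = np.isfinite(delta)
    if defined.sum() < 2 and background_deltas is None:
        raise ValueError("need at least 2 indels with defined indices")
    out = counts.loc[defined].reset_index(drop=True)
    out["indel_index_aa"] = idx_aa[defined]
    out["indel_index_ab"] = idx_ab[defined]
    out["delta"] = delta[defined]
    if background_deltas is None:
        z, _, _, _ = z_scores(out["delta"].to_numpy(), scale=scale)
    else:
        bg = np.asarray(background_deltas, dtype=float)
        bg = bg[np.isfinite(bg)]
        if bg.size < 2:
            raise ValueError("background needs at least 2 defined deltas")
        mu0 = bg.mean()
        s = bg.std(ddof=1)
        if s == 0.0:
            raise ValueError("background deltas are all identical (S = 0)")
        denom = s / np.sqrt(bg.size) if scale == "se" else s
        z = (out["delta"].to_numpy() - mu0) / denom
    out["z_indel"] = z
    out["p_indel"] = p_from_z(z, sided="two")
    return out


def classify(records: pd.DataFrame) -> pd.DataFrame:
    """Positive / false-discovery verdict per putative marker.

    Verdict is "positive" iff the indel's p-value is strictly smaller than
    the marker's own pooled-scan p-value; equality counts against the
    marker.  Rows missing either p are skipped with a warning.
    """
    records = records.copy()
    missing = records["p_bsa"].isna() | records["p_indel"].isna()
    if missing.any():
        logger.warning("skipping %d records with a missing p-value", int(missing.sum()))
        records = records.loc[~missing].reset_index(drop=True)
    records["verdict"] = np.where(
        records["p_indel"] < records["p_bsa"], "positive", "false_discovery"
    )
    n_pos = int((records["verdict"] == "positive").sum())
    logger.info(
        "confirmation: %d positive, %d false discoveries",
        n_pos, len(records) - n_pos,
    )
    return records


def flank_support(
    marker_chrom: str,
    marker_pos: int,
    indel_counts: pd.DataFrame,
    window_bp: int = 30_000,
    alpha: float = 0.05,
    scale: str = "se",
    background_deltas: np.ndarray | None = None,
) -> dict:
    """How many flanking indels are independently significant around a marker.

    Used for single-marker QTLs: a lone linked marker is weak evidence, but a
    run of flanking indels each significant on its own (two-sided p < alpha)
    supports a real locus.  ``indel_counts`` carries both positions and the
    individual genotype counts.  Because the flanking indels of a real QTL
    are themselves a homogeneous linked run, a ``background_deltas`` null
    background (e.g. genotype-count deltas at unlinked markers) should be
    supplied for the significance to be meaningful.
    """
    flanking = find_flanking_indels(marker_chrom, marker_pos, indel_counts, window_bp)
    if flanking.empty:
        return {"n_flanking": 0, "n_significant": 0, "indels": []}
    tested = indel_index_test(flanking, scale=scale, background_deltas=background_deltas)
    significant = tested["p_indel"] < alpha
    return {
        "n_flanking": len(tested),
        "n_significant": int(significant.sum()),
        "indels": tested[["indel_id", "z_indel", "p_indel"]].to_dict("records"),
    }


def confirm_markers(
    scan_table: pd.DataFrame,
    indel_counts: pd.DataFrame,
    scale: str = "se",
    background_deltas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Join a scan's putative markers with their confirmation indels and classify.

    ``scan_table`` needs marker_id and p columns; ``indel_counts`` needs
    indel_id, linked_marker_id and the four count channels.  One indel per
    marker is expected; extras are kept and the nearest-listed wins.
    """
    tested = indel_index_test(indel_counts, scale=scale,
                              background_deltas=background_deltas)
    merged = tested.merge(
        scan_table[["marker_id", "z", "p"]].rename(
            columns={"z": "z_bsa", "p": "p_bsa"}
        ),
        left_on="linked_marker_id",
        right_on="marker_id",
        how="inner",
    )
    merged = merged.drop_duplicates("linked_marker_id", keep="first")
    return classify(merged)
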