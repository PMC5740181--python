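"""Linkage-region definition and candidate-gene screening.

A BC1 design allows only one recombination per gamete, so linkage
disequilibrium around a confirmed marker extends far beyond the marker
itself.  Each confirmed marker therefore anchors a 300 kb window (the
approximate physical span of 1 cM in the silkworm genome, +/-150 kb around
the marker); overlapping windows merge into a single region.  Genes
overlapping a region are collected from the annotation and screened by
expression evidence: a candidate must have EST support in every required
tissue (by default the 5th-instar silk gland, where silk is made, and the
embryo, the other stage that sets silk yield).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TISSUES = ("silk_gland_5th_instar", "embryo")


def define_regions(
    positives: pd.DataFrame,
    half_width_bp: int = 150_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Merged 1-based inclusive windows centered on confirmed markers.

    ``positives`` needs marker_id, chrom, pos.  Windows are clipped at 1 and
    at the chromosome length when known; windows that overlap or touch
    (gap 0) merge, and a merged region records every contributing marker.
    """
    if half_width_bp <= 0:
        raise ValueError("half_width_bp must be positive")
    chrom_sizes = chrom_sizes or {}
    rows = []
    for row in positives.itertuples():
        start = max(1, int(row.pos) - half_width_bp)
        end = int(row.pos) + half_width_bp
        size = chrom_sizes.get(row.chrom)
        if size is not None:
            end = min(end, int(size))
        else:
            logger.warning(
                "no length for chromosome %s; window clipped at 1 only", row.chrom
            )
        rows.append((row.chrom, start, end, row.marker_id))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "marker_id"])
    merged = []
    for chrom, group in windows.groupby("chrom", sort=True):
        group = group.sort_values(["start", "end"], kind="stable")
        cur_start = cur_end = None
        cur_markers: list[str] = []
        for w in group.itertuples():
            if cur_start is None:
                cur_start, cur_end, cur_markers = w.start, w.end, [w.marker_id]
            elif w.start <= cur_end + 1:  # overlap or directly adjacent
                cur_end = max(cur_end, w.end)
                cur_markers.append(w.marker_id)
            else:
                merged.append((chrom, cur_start, cur_end, cur_markers))
                cur_start, cur_end, cur_markers = w.start, w.end, [w.marker_id]
        if cur_start is not None:
            merged.append((chrom, cur_start, cur_end, cur_markers))
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "source_markers"])


def genes_in_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping any region by at least 1 bp, deduplicated.

    Coordinates are 1-based inclusive on both sides, so a gene ending
    exactly at a region start still overlaps.
    """
    hits = []
    for chrom, region_group in regions.groupby("chrom"):
        cand = genes.loc[genes["chrom"] == chrom]
        if cand.empty:
            continue
        for r in region_group.itertuples():
            overlap = cand.loc[(cand["end"] >= r.start) & (cand["start"] <= r.end)]
            hits.append(overlap)
    if not hits:
        return genes.iloc[0:0].copy()
    out = pd.concat(hits).drop_duplicates("gene_id")
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def est_screen(
    genes: pd.DataFrame,
    est_counts: pd.DataFrame,
    required_tissues: tuple[str, ...] = DEFAULT_TISSUES,
) -> pd.DataFrame:
    """Keep genes with EST count > 0 in every required tissue.

    ``est_counts`` is long format (gene_id, tissue, count); a gene missing a
    tissue row is treated as count 0.  The returned table carries one count
    column per tissue for reporting.  With no required tissues the filter is
    vacuous and every gene passes.
    """
    wide = (
        est_counts.pivot_table(
            index="gene_id", columns="tissue", values="count", aggfunc="sum"
        )
        .reindex(genes["gene_id"])
        .fillna(0)
    )
    for tissue in required_tissues:
        if tissue not in wide.columns:
            logger.info("tissue %r absent from EST table; treated as all-zero", tissue)
            wide[tissue] = 0
    keep = pd.Series(True, index=wide.index)
    for tissue in required_tissues:
        keep &= wide[tissue] > 0
    out = genes.set_index("gene_id").loc[keep[keep].index].reset_index()
    counts = wide.loc[out["gene_id"]].reset_index(drop=True)
    counts.columns = [f"est_{c}" for c in counts.columns]
    return pd.concat([out, counts], axis=1)


# ---------------------------------------------------------------------------
# annotation IO

def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene records from GFF3 or BED6 into (gene_id, chrom, start, end, strand).

    BED intervals (0-based half-open) are converted to 1-based inclusive at
    this boundary; GFF3 is already 1-based inclusive.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = [
            (f.id, f.seqid, f.start, f.end, f.strand)
            for f in db.features_of_type("gene")
        ]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6),
    )
    return pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"],
            "start": bed["start"] + 1,
            "end": bed["end"],
            "strand": bed["strand"],
        }
    )


def regions_to_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write regions as BED (converting to 0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"] - 1,
            "end": regions["end"],
            "name": [
                ";".join(m) if isinstance(m, list) else str(m)
                for m in regions.get("source_markers", regions.index.astype(str))
            ],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
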