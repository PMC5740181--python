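import numpy as np
import pandas as pd
import pytest

from poolscan import simulate
from poolscan.worked_example import confirmation_table


@pytest.fixture(scope="session")
def table1():
    """The published 14-marker confirmation table."""
    return confirmation_table()


@pytest.fixture(scope="session")
def small_population():
    """A small BC1 population with one strong planted QTL (shared, read-only)."""
    design = simulate.CrossDesign(
        n_families=4,
        family_size_range=(100, 100),
        chromosomes={"chr1": 50.0, "chr2": 50.0},
        qtl=[("chr1", 25.0, 0.10)],
        marker_spacing_cm=2.0,
        seed=7,
    )
    return simulate.simulate_bc1(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def brute_force_overlap(regions: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """All-pairs 1-based inclusive overlap check (oracle for genes_in_regions)."""
    hits = set()
    for g in genes.itertuples():
        for r in regions.itertuples():
            if g.chrom == r.chrom and g.end >= r.start and g.start <= r.end:
                hits.add(g.gene_id)
    return hits


def brute_force_runs(degs: pd.DataFrame, cutoff: float) -> list[list[str]]:
    """Enumerate maximal >=3 runs with all gaps strictly below cutoff (oracle)."""
    out = []
    for chrom in sorted(degs["chrom"].unique()):
        sub = degs.loc[degs["chrom"] == chrom].sort_values("pos", kind="stable")
        ids = sub["gene_id"].tolist()
        pos = sub["pos"].tolist()
        i = 0
        while i < len(pos):
            j = i
            while j + 1 < len(pos) and pos[j + 1] - pos[j] < cutoff:
                j += 1
            if j - i + 1 >= 3:
                out.append(ids[i : j + 1])
            i = j + 1
    return out
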