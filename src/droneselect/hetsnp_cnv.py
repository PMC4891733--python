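"""CNV candidates from clustered heterozygous calls in haploid drones.

A heterozygous genotype in a haploid drone is impossible at a unique
locus; clusters of such calls with inflated depth are the signature of
collapsed duplications in the reference assembly.  The detector applies
the filter cascade: sites with DP ≥ 9 in every individual on chromosomes
1–16, per-drone removal of hetSNPs > 2 kb from their nearest het
neighbour, retention of clusters with ≥ 3 hetSNPs spanning ≥ 2 kb at mean
depth ≥ 3× the drone's average, union of overlapping clusters across
drones, and a Pearson chi-squared test for population bias in carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, HET, Interval, MISSING, SampleTable

logger = logging.getLogger(__name__)

AUTOSOMES = {str(i) for i in range(1, 17)}


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class HetSnpCluster:
    """A run of clustered hetSNPs in one drone."""

    drone_id: str
    chrom: str
    start: int
    end: int
    n_het: int
    mean_dp: float
    drone_mean_dp: float

    def __post_init__(self):
        if self.n_het < 3 or self.end - self.start < 2000:
            raise ValueError("cluster violates n_het >= 3 / span >= 2 kb")


@dataclass
class ClusterInterval:
    """Union of overlapping per-drone clusters with population carrier counts."""

    chrom: str
    start: int
    end: int
    carriers: dict[str, int] = field(default_factory=dict)
    total_carriers: int = 0
    carrier_ids: list[str] = field(default_factory=list)
    chi2: float | None = None
    p_value: float | None = None
    overlaps_recombination: bool = False
    nearby_genes: list[str] = field(default_factory=list)
    flagged_frequent: bool = False


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def site_filter(
    gm: GenotypeMatrix, dp_min: int = 9, chroms: set | None = None
) -> GenotypeMatrix:
    """Keep sites on the autosomes where every sample has DP ≥ ``dp_min``."""
    chroms = AUTOSOMES if chroms is None else {str(c) for c in chroms}
    keep = (gm.depth >= dp_min).all(axis=0)
    keep &= gm.sites["chrom"].astype(str).isin(chroms).to_numpy()
    return gm.subset_sites(keep)


def neighbor_filter(positions: np.ndarray, max_gap: int = 2000) -> np.ndarray:
    """Retain positions whose nearest neighbour (same chromosome) is ≤ max_gap."""
    pos = np.sort(np.asarray(positions, dtype=int))
    if pos.size < 2:
        return np.empty(0, dtype=int)
    gap_prev = np.diff(pos, prepend=pos[0] - max_gap - 1)
    gap_next = np.diff(pos, append=pos[-1] + max_gap + 1)
    return pos[(gap_prev <= max_gap) | (gap_next <= max_gap)]


def call_clusters(
    het_positions: np.ndarray,
    het_depths: np.ndarray,
    drone_id: str,
    chrom: str,
    drone_mean_dp: float,
    min_n: int = 3,
    min_span: int = 2000,
    dp_factor: float = 3.0,
    max_gap: int = 2000,
) -> list[HetSnpCluster]:
    """Form maximal runs of retained hets (gaps ≤ max_gap) and filter.

    ``het_positions``/``het_depths`` are the retained hetSNPs of one drone
    on one chromosome (post :func:`neighbor_filter`); ``drone_mean_dp`` is
    the drone's genome-wide average depth over all genotyped sites.
    """
    pos = np.asarray(het_positions, dtype=int)
    dp = np.asarray(het_depths, dtype=float)
    order = np.argsort(pos)
    pos, dp = pos[order], dp[order]
    clusters = []
    if pos.size == 0:
        return clusters
    s = 0
    for i in range(1, pos.size + 1):
        if i == pos.size or pos[i] - pos[i - 1] > max_gap:
            run_pos, run_dp = pos[s:i], dp[s:i]
            n = run_pos.size
            span = int(run_pos[-1] - run_pos[0])
            mdp = float(run_dp.mean())
            if n >= min_n and span >= min_span and mdp >= dp_factor * drone_mean_dp:
                clusters.append(
                    HetSnpCluster(
                        drone_id, chrom, int(run_pos[0]), int(run_pos[-1]), n, mdp,
                        drone_mean_dp,
                    )
                )
            s = i
    return clusters


def detect_clusters(
    gm: GenotypeMatrix,
    dp_min: int = 9,
    min_n: int = 3,
    min_span: int = 2000,
    dp_factor: float = 3.0,
    max_gap: int = 2000,
    chroms: set | None = None,
) -> list[HetSnpCluster]:
    """Per-drone hetSNP cluster calling over a genotype matrix.

    The drone-average depth baseline is computed over all the drone's
    genotyped (non-missing) sites *before* the DP site filter.
    """
    called = gm.calls != MISSING
    with np.errstate(invalid="ignore"):
        drone_mean = np.where(
            called.sum(axis=1) > 0,
            (gm.depth * called).sum(axis=1) / np.maximum(called.sum(axis=1), 1),
            0.0,
        )
    filt = site_filter(gm, dp_min=dp_min, chroms=chroms)
    chrom_arr = filt.sites["chrom"].astype(str).to_numpy()
    pos_arr = filt.sites["pos"].to_numpy()
    clusters: list[HetSnpCluster] = []
    for i, drone in enumerate(gm.samples.sample_ids):
        is_het = filt.calls[i] == HET
        for c in dict.fromkeys(chrom_arr):
            m = is_het & (chrom_arr == c)
            pos = pos_arr[m]
            dps = filt.depth[i][m]
            kept = neighbor_filter(pos, max_gap=max_gap)
            keep_mask = np.isin(pos, kept)
            clusters.extend(
                call_clusters(
                    pos[keep_mask],
                    dps[keep_mask],
                    drone,
                    c,
                    float(drone_mean[i]),
                    min_n=min_n,
                    min_span=min_span,
                    dp_factor=dp_factor,
                    max_gap=max_gap,
                )
            )
    return clusters


# ---------------------------------------------------------------------------
# merging across drones
# ---------------------------------------------------------------------------


def merge_across_drones(
    clusters: list[HetSnpCluster],
    sample_table: SampleTable,
    carrier_threshold: int = 15,
) -> list[ClusterInterval]:
    """Union per-drone clusters overlapping by ≥ 1 bp into intervals.

    Carrier counts are tallied per population; intervals with total
    carriers > ``carrier_threshold`` are flagged (the "present in > 15
    drones" rule of the 60-drone design).  Output is independent of the
    input cluster order.
    """
    pop_of = dict(
        zip(sample_table.df["sample_id"].astype(str), sample_table.df["population"])
    )
    out: list[ClusterInterval] = []
    by_chrom: dict[str, list[HetSnpCluster]] = {}
    for cl in clusters:
        by_chrom.setdefault(str(cl.chrom), []).append(cl)
    for chrom in sorted(by_chrom):
        cls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end, c.drone_id))
        cur = [cls[0]]
        cur_end = cls[0].end
        groups = []
        for cl in cls[1:]:
            if cl.start <= cur_end:  # >= 1 bp overlap (1-based inclusive)
                cur.append(cl)
                cur_end = max(cur_end, cl.end)
            else:
                groups.append(cur)
                cur = [cl]
                cur_end = cl.end
        groups.append(cur)
        for grp in groups:
            ids = sorted({c.drone_id for c in grp})
            counts: dict[str, int] = {}
            for d in ids:
                counts[pop_of[d]] = counts.get(pop_of[d], 0) + 1
            out.append(
                ClusterInterval(
                    chrom=chrom,
                    start=min(c.start for c in grp),
                    end=max(c.end for c in grp),
                    carriers=counts,
                    total_carriers=len(ids),
                    carrier_ids=ids,
                    flagged_frequent=len(ids) > carrier_threshold,
                )
            )
    return out


# ---------------------------------------------------------------------------
# population bias test
# ---------------------------------------------------------------------------


def population_bias_test(
    carrier_counts: dict[str, int], n_per_population: dict[str, int]
):
    """Pearson chi-squared (no continuity correction) on carriers × population.

    Returns ``(chi2, p)`` with p from the χ² upper tail at
    ``len(populations) − 1`` degrees of freedom.
    """
    pops = list(n_per_population)
    if any(n_per_population[p] <= 0 for p in pops):
        zero = [p for p in pops if n_per_population[p] <= 0]
        raise ValueError(f"population(s) with zero samples: {zero}")
    carriers = np.array([carrier_counts.get(p, 0) for p in pops], dtype=float)
    totals = np.array([n_per_population[p] for p in pops], dtype=float)
    if (carriers > totals).any():
        raise ValueError("carrier count exceeds population size")
    table = np.vstack([carriers, totals - carriers])
    if table.sum(axis=1).min() == 0:
        # all carriers or all non-carriers: no association testable
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def test_intervals(
    intervals: list[ClusterInterval], sample_table: SampleTable
) -> list[ClusterInterval]:
    """Run the population bias test on every interval in place."""
    n_per_pop = {
        p: int(len(sample_table.indices_of(p))) for p in sample_table.populations
    }
    for iv in intervals:
        iv.chi2, iv.p_value = population_bias_test(iv.carriers, n_per_pop)
    return intervals


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def annotate(
    intervals: list[ClusterInterval],
    recomb_intervals: list[Interval] | None = None,
    genes: list[Interval] | None = None,
    gene_margin: int = 2000,
) -> list[ClusterInterval]:
    """Flag recombination-event overlap and list genes within ``gene_margin``."""
    from intervaltree import IntervalTree

    def build_trees(ivs):
        trees: dict[str, IntervalTree] = {}
        for iv in ivs:
            # half-open internal tree coordinates
            trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end + 1, iv.name
            )
        return trees

    rec_trees = build_trees(recomb_intervals or [])
    gene_trees = build_trees(genes or [])
    for civ in intervals:
        t = rec_trees.get(civ.chrom)
        civ.overlaps_recombination = bool(t and t.overlap(civ.start, civ.end + 1))
        g = gene_trees.get(civ.chrom)
        if g:
            hits = g.overlap(civ.start - gene_margin, civ.end + gene_margin + 1)
            civ.nearby_genes = sorted({h.data for h in hits if h.data})
        else:
            civ.nearby_genes = []
    return intervals


def intervals_to_frame(intervals: list[ClusterInterval]) -> pd.DataFrame:
    rows = []
    for iv in intervals:
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "total_carriers": iv.total_carriers,
                **{f"n_{p}": c for p, c in sorted(iv.carriers.items())},
                "chi2": iv.chi2,
                "p_value": iv.p_value,
                "overlaps_recombination": iv.overlaps_recombination,
                "nearby_genes": ";".join(iv.nearby_genes),
                "flagged_frequent": iv.flagged_frequent,
            }
        )
    return pd.DataFrame(rows)
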