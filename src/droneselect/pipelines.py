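"""End-to-end replicate protocols tying the generators to the scans.

These are the standard positive/negative-control experiments for the
three analysis paths: a selective sweep that the hapFLK scan must locate
and assign, a collapsed duplication that the hetSNP cluster caller must
recover (and must not hallucinate on null data), and a mitotype read set
whose source accession the panel scoring must identify.  Each replicate
is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import flk as flk_mod
from . import hetsnp_cnv as hc
from . import mitotype as mt
from . import popstats
from . import synthetic_data as sd


@dataclass
class SweepReplicate:
    region_overlaps_truth: bool
    assigned_to_swept: bool
    n_regions: int
    sweep_start: int
    sweep_end: int


def sweep_replicate(
    seed: int,
    nsites: int = 5000,
    nsamples: int = 30,
    K: int = 10,
    n_fits: int = 5,
    sweep_strength: float = 0.9,
    alpha: float = 1e-4,
) -> SweepReplicate:
    """Simulate 3 ingroup populations + outgroup, sweep one, scan, assign.

    The kinship used by the scan is estimated from the data (Reynolds
    distances, NJ tree rooted on the outgroup), exactly as the file-based
    pipeline does.
    """
    F = sd.four_population_kinship()
    model = sd.DriftModel(npop=4, kinship_true=F, nsites=nsites, seed=seed)
    freqs, _ = sd.simulate_frequencies(model)
    labels = ["HN", "RJ", "SL", "OU"]
    gm = sd.simulate_haplotypes(
        freqs, nsamples, seed=seed + 1000, pop_labels=labels
    )
    pos = gm.sites["pos"]
    mid = int(pos.iloc[len(pos) // 2])
    spec = sd.SweepSpec("RJ", "1", mid, mid + 20_000, sweep_strength)
    gm = sd.inject_sweep(gm, spec, seed=seed + 2000)

    kin = popstats.kinship_from_genotypes(gm, "OU")
    ingroup = np.flatnonzero(
        gm.samples.df["population"].isin(kin.populations).to_numpy()
    )
    gmi = gm.subset_samples(ingroup)
    res = flk_mod.flk_scan_genotypes(gmi, kin)

    haps = flk_mod.haplotypes_from_gm(gmi)
    pops_arr = gmi.samples.df["population"].to_numpy()
    models = flk_mod.fit_cluster_model(haps, K=K, n_fits=n_fits, seed=seed + 3000)
    hap_vals = flk_mod.hapflk_statistic(models, haps, pops_arr, kin)
    pvals, _, _ = flk_mod.pvalues_from_chi2(hap_vals)
    regions = flk_mod.call_regions(
        gmi.sites["chrom"].to_numpy(), gmi.sites["pos"].to_numpy(), pvals,
        alpha=alpha,
    )
    regions = flk_mod.assign_populations(regions, res)
    hit = any(r.start <= spec.end and spec.start <= r.end for r in regions)
    assigned = any(
        r.start <= spec.end and spec.start <= r.end
        and r.assigned_population == "RJ"
        for r in regions
    )
    return SweepReplicate(hit, assigned, len(regions), spec.start, spec.end)


@dataclass
class CnvReplicate:
    segment_recovered: bool
    n_intervals: int
    clusters_valid: bool


def cnv_replicate(seed: int, inject: bool = True, nsites: int = 3000,
                  nsamples: int = 30) -> CnvReplicate:
    """Simulate two-population drones, optionally inject a duplication.

    Returns whether an emitted interval overlaps the injected segment
    (which lies entirely inside it by construction of cluster spans), the
    number of intervals, and whether every emitted cluster re-satisfies
    the three filter predicates when re-checked independently.
    """
    model = sd.DriftModel(nsites=nsites, seed=seed)
    freqs, _ = sd.simulate_frequencies(model)
    gm = sd.simulate_haplotypes(
        freqs, nsamples, seed=seed + 1, pop_labels=["HN", "RJ", "SL"]
    )
    pos = gm.sites["pos"]
    start = int(pos.iloc[len(pos) // 3])
    spec = sd.CnvSpec(
        "1", start, start + 10_000,
        carrier_fraction={"HN": 0.3, "RJ": 0.7},
        min_realized_hets=3,
    )
    if inject:
        gm, _ = sd.inject_cnv(gm, spec, seed=seed + 2)
    clusters = hc.detect_clusters(gm)
    intervals = hc.merge_across_drones(clusters, gm.samples)
    hc.test_intervals(intervals, gm.samples)
    hit = any(
        iv.chrom == "1" and iv.start <= spec.end and spec.start <= iv.end
        for iv in intervals
    )
    called = gm.calls != -1
    valid = True
    for cl in clusters:
        i = gm.samples.sample_ids.index(cl.drone_id)
        baseline = gm.depth[i][called[i]].mean()
        valid &= (
            cl.n_het >= 3
            and cl.end - cl.start >= 2000
            and cl.mean_dp >= 3 * baseline - 1e-9
        )
    return CnvReplicate(hit, len(intervals), bool(valid))


def mitotype_replicate(seed: int, read_error_rate: float = 0.005,
                       coverage: float = 20.0) -> bool:
    """Simulate one mitotype + decoy panel; True if the truth is selected."""
    rng = np.random.default_rng(seed)
    spec = sd.MitoSimSpec(
        p_element_present=bool(rng.integers(0, 2)),
        q_copies=int(rng.integers(1, 4)),
        snp_positions=[20 + int(p) for p in rng.choice(80, size=2, replace=False)],
        snp_alleles=[str(b) for b in rng.choice(list("ACGT"), size=2)],
        read_error_rate=read_error_rate,
        coverage=coverage,
    )
    sim = sd.simulate_mito(spec, seed=seed + 50_000)
    panel = mt.MitotypePanel.from_raw(sim["panel"])
    matches = mt.score_against_panel(sim["reads"], panel)
    best = mt.select_best(matches)
    return best.accession == sim["truth_accession"]
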