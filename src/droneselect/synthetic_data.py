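"""Synthetic inputs with the statistical structure the analyses assume.

Four generators cover the four analysis paths:

* hierarchical drift: population allele frequencies drawn per site from a
  Gaussian with covariance ``p0 (1 - p0) F`` around an ancestral frequency
  ``p0`` — exactly the model behind the FLK statistic, so null calibration
  of the test is a fair check;
* haploid haplotypes with block LD from small per-population founder pools,
  plus a realistic per-call depth model;
* selective sweeps (one haplotype driven to high frequency in one
  population) and collapsed duplications (hetSNP clusters with inflated
  depth in carrier drones);
* mitotype sequences assembled from anchor/P/Q elements with point
  mutations, and error-bearing reads from them.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ALT, HET, MISSING, REF, GenotypeMatrix, SampleTable

# ---------------------------------------------------------------------------
# drift model
# ---------------------------------------------------------------------------

#: Default co-ancestry for three managed populations of one lineage that
#: share a little ancestral branch length: a moderately drifted
#: honey-production-like population, a strongly bottlenecked
#: closed-breeding population (royal-jelly-like: such populations separate
#: first in structure analyses), and a larger reference population.
DEFAULT_KINSHIP = np.array(
    [
        [0.030, 0.010, 0.010],
        [0.010, 0.080, 0.010],
        [0.010, 0.010, 0.020],
    ]
)

#: Default outgroup drift (a distinct evolutionary lineage).
OUTGROUP_DIAG = 0.15


def four_population_kinship(
    kin3: np.ndarray | None = None, outgroup_diag: float = OUTGROUP_DIAG
) -> np.ndarray:
    """Three ingroup populations plus an unrelated outgroup lineage."""
    kin3 = DEFAULT_KINSHIP if kin3 is None else np.asarray(kin3, float)
    n = kin3.shape[0]
    F = np.zeros((n + 1, n + 1))
    F[:n, :n] = kin3
    F[n, n] = outgroup_diag
    return F


def _uniform_p0(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(0.05, 0.95, size=n)


@dataclass
class DriftModel:
    """Pure-drift model: p ~ N(p0 * 1, p0 (1 - p0) F), truncated to [0, 1]."""

    npop: int = 3
    kinship_true: np.ndarray = field(default_factory=lambda: DEFAULT_KINSHIP.copy())
    p0_distribution: Callable[[np.random.Generator, int], np.ndarray] = _uniform_p0
    nsites: int = 20_000
    seed: int = 0

    def __post_init__(self):
        F = np.asarray(self.kinship_true, dtype=float)
        if F.shape != (self.npop, self.npop):
            raise ValueError("kinship_true must be npop x npop")
        if not np.allclose(F, F.T, atol=1e-10):
            raise ValueError("kinship_true must be symmetric")
        w = np.linalg.eigvalsh(F)
        if w.min() < -1e-10:
            raise ValueError("kinship_true must be positive semi-definite")
        if (np.diag(F) < 0).any() or (np.diag(F) >= 1).any():
            raise ValueError("diagonal of kinship_true must be in [0, 1)")
        self.kinship_true = F


def simulate_frequencies(model: DriftModel):
    """Draw per-population allele frequencies under hierarchical drift.

    Returns ``(freqs, p0)`` with ``freqs`` of shape (npop, nsites).  Sites
    where any population frequency leaves [0, 1] (and would be truncated,
    putting a point mass on the boundary that is foreign to the Gaussian
    drift null) are redrawn up to 10 times; the rare survivors of all
    retries are clipped.
    """
    rng = np.random.default_rng(model.seed)
    F = model.kinship_true
    w, V = np.linalg.eigh(F)
    A = V @ np.diag(np.sqrt(np.clip(w, 0, None)))  # F = A A'

    def draw(n):
        p0 = model.p0_distribution(rng, n)
        z = rng.standard_normal((model.npop, n))
        scale = np.sqrt(p0 * (1 - p0))
        p = p0[None, :] + scale[None, :] * (A @ z)
        return p, p0

    freqs, p0 = draw(model.nsites)
    for _ in range(10):
        bad = np.flatnonzero(((freqs <= 0) | (freqs >= 1)).any(axis=0))
        if bad.size == 0:
            break
        freqs[:, bad], p0[bad] = draw(bad.size)
    return np.clip(freqs, 0.0, 1.0), p0


# ---------------------------------------------------------------------------
# haplotypes with block LD
# ---------------------------------------------------------------------------


def simulate_haplotypes(
    freqs: np.ndarray,
    nsamples_per_pop: int | Sequence[int],
    ld_blocks: int = 20,
    seed: int = 0,
    n_founders: int = 16,
    chrom: str = "1",
    spacing: int = 200,
    positions: np.ndarray | None = None,
    pop_labels: Sequence[str] | None = None,
    mean_depth: float = 12.0,
    het_noise_rate: float = 0.005,
) -> GenotypeMatrix:
    """Draw haploid genotypes with block LD from per-population founder pools.

    Within each LD block of ``ld_blocks`` consecutive sites, ``n_founders``
    founder haplotypes per population are drawn site-wise Bernoulli from
    ``freqs``; each sample copies one founder per block (block boundaries
    act as recombination points).  Depth is ``round(drone_mean * site
    multiplier)`` with the multiplier shared across drones at a site,
    mimicking mappability-driven depth correlation.  A small fraction of
    calls (``het_noise_rate``) is flipped to heterozygous, mimicking
    mapping-artefact hetSNP noise in haploid callers.
    """
    if ld_blocks < 1:
        raise ValueError("ld_blocks must be >= 1")
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    npop, nsites = freqs.shape
    if np.isscalar(nsamples_per_pop):
        nsamp = [int(nsamples_per_pop)] * npop
    else:
        nsamp = list(nsamples_per_pop)
    if pop_labels is None:
        pop_labels = [f"P{i + 1}" for i in range(npop)]

    if positions is None:
        positions = np.arange(1, nsites + 1) * spacing
    positions = np.asarray(positions, dtype=int)
    if positions.size != nsites:
        raise ValueError("positions length must match number of sites")

    starts = np.arange(0, nsites, ld_blocks)
    calls = []
    for p in range(npop):
        n = nsamp[p]
        hap = np.empty((n, nsites), dtype=np.int8)
        for s in starts:
            e = min(s + ld_blocks, nsites)
            pool = (
                rng.random((n_founders, e - s)) < freqs[p, s:e]
            ).astype(np.int8)
            choice = rng.integers(0, n_founders, size=n)
            hap[:, s:e] = pool[choice]
        calls.append(hap)
    calls = np.vstack(calls)
    ntot = calls.shape[0]

    # depth: per-drone mean x per-site multiplier (shared across drones)
    drone_mean = rng.normal(mean_depth, 1.0, size=ntot).clip(min=1.0)
    site_mult = rng.gamma(shape=30.0, scale=1.0 / 30.0, size=nsites)
    depth = np.rint(drone_mean[:, None] * site_mult[None, :]).astype(np.int32)
    depth = np.clip(depth, 0, None)

    if het_noise_rate > 0:
        noise = rng.random(calls.shape) < het_noise_rate
        calls = np.where(noise, HET, calls).astype(np.int8)

    sample_ids = []
    pops = []
    for p in range(npop):
        for i in range(nsamp[p]):
            sample_ids.append(f"{pop_labels[p]}{i + 1:02d}")
            pops.append(pop_labels[p])
    table = SampleTable.from_records(sample_ids, pops, ploidy=1)
    ref = np.full(nsites, "A")
    alt = np.full(nsites, "G")
    sites = pd.DataFrame(
        {"chrom": str(chrom), "pos": positions, "ref": ref, "alt": alt}
    )
    return GenotypeMatrix(sites, calls, depth, table)


# ---------------------------------------------------------------------------
# sweep injection
# ---------------------------------------------------------------------------


@dataclass
class SweepSpec:
    """A selective sweep: one resident haplotype raised to high frequency."""

    target_population: str
    chrom: str
    start: int
    end: int
    sweep_strength: float = 0.9

    def __post_init__(self):
        if not (0 < self.sweep_strength <= 1):
            raise ValueError("sweep_strength must be in (0, 1]")
        if self.end < self.start:
            raise ValueError("end < start")


def inject_sweep(gm: GenotypeMatrix, spec: SweepSpec, seed: int = 0) -> GenotypeMatrix:
    """Copy one random resident haplotype over others in the sweep window."""
    rng = np.random.default_rng(seed)
    in_win = (
        (gm.sites["chrom"].astype(str) == str(spec.chrom))
        & (gm.sites["pos"] >= spec.start)
        & (gm.sites["pos"] <= spec.end)
    ).to_numpy()
    if not in_win.any():
        raise ValueError("sweep window contains no sites")
    pop_idx = gm.samples.indices_of(spec.target_population)
    if pop_idx.size == 0:
        raise ValueError(f"no samples in population {spec.target_population}")
    calls = gm.calls.copy()
    win = np.flatnonzero(in_win)
    donor = rng.choice(pop_idx)
    donor_hap = calls[donor][win]
    identical = np.array(
        [np.array_equal(calls[i][win], donor_hap) for i in pop_idx]
    )
    target_count = math.ceil(spec.sweep_strength * pop_idx.size)
    need = target_count - identical.sum()
    if need > 0:
        others = pop_idx[~identical]
        chosen = rng.choice(others, size=need, replace=False)
        for i in chosen:
            calls[i, win] = donor_hap
    return GenotypeMatrix(gm.sites, calls, gm.depth, gm.samples)


# ---------------------------------------------------------------------------
# CNV injection
# ---------------------------------------------------------------------------


@dataclass
class CnvSpec:
    """A collapsed duplication: het calls plus inflated depth in carriers."""

    chrom: str
    start: int
    end: int
    carrier_fraction: dict[str, float] = field(default_factory=dict)
    paralog_divergence: float = 0.15
    depth_inflation_factor: float = 3.0
    min_realized_hets: int = 0

    def __post_init__(self):
        if self.depth_inflation_factor < 1:
            raise ValueError("depth_inflation_factor must be >= 1")
        for pop, f in self.carrier_fraction.items():
            if not (0 <= f <= 1):
                raise ValueError(f"carrier_fraction[{pop}] out of [0, 1]")


def inject_cnv(gm: GenotypeMatrix, spec: CnvSpec, seed: int = 0):
    """Inject a duplicated segment; returns ``(matrix, carriers)``.

    Carrier drones (a per-population fraction, rounded) gain heterozygous
    calls at segment sites with probability ``paralog_divergence`` and have
    their depth multiplied by ``depth_inflation_factor`` inside the
    segment.  Non-carriers are untouched.  If ``min_realized_hets`` > 0 the
    generator asserts every carrier realised at least that many het calls.
    """
    rng = np.random.default_rng(seed)
    in_seg = (
        (gm.sites["chrom"].astype(str) == str(spec.chrom))
        & (gm.sites["pos"] >= spec.start)
        & (gm.sites["pos"] <= spec.end)
    ).to_numpy()
    seg = np.flatnonzero(in_seg)
    calls = gm.calls.copy()
    depth = gm.depth.copy()
    carriers: list[int] = []
    for pop, frac in spec.carrier_fraction.items():
        idx = gm.samples.indices_of(pop)
        k = int(round(frac * idx.size))
        if k > 0:
            carriers.extend(rng.choice(idx, size=k, replace=False).tolist())
    for i in carriers:
        hets = seg[rng.random(seg.size) < spec.paralog_divergence]
        # the requested het density is a study condition: redraw a carrier's
        # diverged positions (bounded) until the minimum count is realised
        for _ in range(20):
            if not spec.min_realized_hets or hets.size >= spec.min_realized_hets:
                break
            hets = seg[rng.random(seg.size) < spec.paralog_divergence]
        if spec.min_realized_hets and hets.size < spec.min_realized_hets:
            raise RuntimeError(
                f"carrier {gm.samples.sample_ids[i]} realised only {hets.size} "
                f"het calls (< {spec.min_realized_hets}); increase site density "
                "or paralog_divergence"
            )
        calls[i, hets] = HET
        depth[i, seg] = np.rint(
            depth[i, seg] * spec.depth_inflation_factor
        ).astype(np.int32)
    out = GenotypeMatrix(gm.sites, calls, depth, gm.samples)
    return out, sorted(carriers)


# ---------------------------------------------------------------------------
# mitotype simulation
# ---------------------------------------------------------------------------

ANCHOR_5 = "CTTTTATTAAA"  # 3' end of tRNA-Leu
ANCHOR_3 = "ATTTCCACA"  # 5' end of COX2

# Synthetic stand-ins for the P and Q sequence elements of the
# tRNA-Leu–cox2 intergenic region (realistic lengths: P ~54 bp, Q ~192 bp).
# These are randomly generated sequences, not GenBank material.
P_ELEMENT = (
    "TTAATAAATTAATATTTAATTTATTATTAAATTAATTTATTAAATATTTATTTA"
)
Q_ELEMENT = (
    "ATTTATTAATTTAATTATAAATTAATTTATTATAAATTTAATTATTAAATTTAT"
    "TAATTAATTTATTAAATATTAATTTATTAATTTAATATTAATTTATTAAATTAA"
    "TTTATTATAAATTAATTATTAAATTTATTAATTAATTTATTAAATATTAATTTA"
    "TTAATTTAATATTAATTTATTAAATTAATTTATT"
)

@dataclass
class MitoSimSpec:
    """Architecture and read-simulation parameters for one mitotype."""

    p_element_present: bool = True
    q_copies: int = 1
    snp_positions: Sequence[int] = ()
    snp_alleles: Sequence[str] = ()
    read_length: int = 100
    read_error_rate: float = 0.005
    mean_quality: int = 33
    quality_sd: float = 2.0
    coverage: float = 20.0

    def __post_init__(self):
        if self.q_copies < 1:
            raise ValueError("q_copies must be >= 1")
        if not (0 <= self.read_error_rate < 1):
            raise ValueError("read_error_rate must be in [0, 1)")
        if len(self.snp_positions) != len(self.snp_alleles):
            raise ValueError("snp_positions and snp_alleles length mismatch")


@dataclass
class FastqRead:
    name: str
    seq: str
    qual: np.ndarray  # phred scores

    @property
    def qual_str(self) -> str:
        return "".join(chr(q + 33) for q in self.qual)


def build_mitotype_sequence(spec: MitoSimSpec) -> str:
    """Assemble anchor + (P) + Q×n + anchor with injected point mutations."""
    core = (P_ELEMENT if spec.p_element_present else "") + Q_ELEMENT * spec.q_copies
    seq = ANCHOR_5 + core + ANCHOR_3
    chars = list(seq)
    for pos, allele in zip(spec.snp_positions, spec.snp_alleles):
        if not (len(ANCHOR_5) <= pos < len(seq) - len(ANCHOR_3)):
            raise ValueError(f"SNP position {pos} falls in an anchor")
        chars[pos] = allele
    return "".join(chars)


def default_panel_builder(
    truth: str,
    rng: np.random.Generator,
    n_decoys: int = 10,
    min_edits: int = 2,
    spec: "MitoSimSpec | None" = None,
) -> list[tuple[str, str]]:
    """Truth plus decoys emulating a real mitotype panel.

    Real mitotypes differ by element architecture (P presence, Q tandem
    copy number) and by point mutations carried in *every* Q copy (a
    variant present before duplication is duplicated with it).  Decoys are
    therefore built from modified element templates rather than by editing
    single bases of the assembled sequence — a single-copy edit inside a
    tandem repeat is invisible to local alignment (reads align to the
    unedited copy) and would make the benchmark test alignment shadowing
    instead of mitotype selection.  Each decoy differs from the truth by
    >= ``min_edits`` substitutions in its element templates, by a whole
    element, or both.  Entries keep their anchors (they emulate raw
    GenBank records and are trimmed downstream); accessions are synthetic.
    """
    entries = [("SYN000", truth)]
    seen = {truth}
    base = spec if spec is not None else MitoSimSpec()

    def assemble(p_present, q_copies, p_seq, q_seq):
        return ANCHOR_5 + (p_seq if p_present else "") + q_seq * q_copies + ANCHOR_3

    def subs(seq, n):
        chars = list(seq)
        for i in rng.choice(len(chars), size=n, replace=False):
            cur = chars[i]
            chars[i] = [b for b in "ACGT" if b != cur][int(rng.integers(0, 3))]
        return "".join(chars)

    i = 1
    while len(entries) < n_decoys + 1:
        kind = int(rng.integers(0, 3))
        n_edits = int(rng.integers(min_edits, min_edits + 3))
        p_present, q_copies = base.p_element_present, base.q_copies
        p_seq, q_seq = P_ELEMENT, Q_ELEMENT
        if kind == 0:  # Q copy-number variant (plus template edits)
            q_copies = q_copies + 1 if q_copies == 1 else q_copies - 1
            q_seq = subs(Q_ELEMENT, n_edits)
        elif kind == 1:  # P presence variant (plus template edits)
            p_present = not p_present
            q_seq = subs(Q_ELEMENT, n_edits)
        else:  # same architecture, diagnostic substitutions in templates
            q_seq = subs(Q_ELEMENT, n_edits)
            if p_present:
                p_seq = subs(P_ELEMENT, n_edits)
        decoy = assemble(p_present, q_copies, p_seq, q_seq)
        if decoy in seen:
            continue
        seen.add(decoy)
        entries.append((f"SYN{i:03d}", decoy))
        i += 1
    return entries


def simulate_mito(
    spec: MitoSimSpec,
    seed: int = 0,
    panel_builder=default_panel_builder,
):
    """Simulate (truth sequence, reads, raw reference panel).

    Reads are drawn with uniform start positions fully inside the truth
    sequence, with substitution errors at ``read_error_rate`` and Phred
    qualities from a Normal(mean_quality, quality_sd) profile.  Returns a
    dict with keys ``truth_seq``, ``truth_accession``, ``reads``, ``panel``.
    """
    if spec.coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = np.random.default_rng(seed)
    truth = build_mitotype_sequence(spec)
    try:
        panel = panel_builder(truth, rng, spec=spec)
    except TypeError:
        panel = panel_builder(truth, rng)

    L = len(truth)
    rl = min(spec.read_length, L)
    n_reads = math.ceil(spec.coverage * L / rl)
    reads = []
    truth_arr = np.array(list(truth))
    for k in range(n_reads):
        start = int(rng.integers(0, L - rl + 1))
        bases = truth_arr[start: start + rl].copy()
        errs = np.flatnonzero(rng.random(rl) < spec.read_error_rate)
        for i in errs:
            options = [b for b in "ACGT" if b != bases[i]]
            bases[i] = options[int(rng.integers(0, 3))]
        qual = np.clip(
            np.rint(rng.normal(spec.mean_quality, spec.quality_sd, size=rl)), 2, 41
        ).astype(int)
        reads.append(FastqRead(f"read{k:05d}/{start}", "".join(bases), qual))
    return {
        "truth_seq": truth,
        "truth_accession": panel[0][0],
        "reads": reads,
        "panel": panel,
    }


# ---------------------------------------------------------------------------
# writers for the file-based interface
# ---------------------------------------------------------------------------


def write_fastq(reads: Sequence[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual_str}\n")


def write_fasta(entries: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
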