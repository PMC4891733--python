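"""FLK and hapFLK selection scans with spectral population assignment.

The FLK statistic tests a vector of population allele frequencies p
against the drift expectation around an estimated ancestral frequency p0,
weighting deviations by the inverse co-ancestry matrix F:

    T = (p − p̂0·1)' [p̂0 (1 − p̂0) F]⁻¹ (p − p̂0·1)

Decomposing F = Q' D Q (Q orthogonal, D the eigenvalues) rewrites
T = Σ u_i² with u = D^{−1/2} Q p̃, so each eigenvector of F contributes
an identifiable share of the signal; large loadings |Q_{i,j}| tie an
eigenvector to a population, which is how significant regions are
assigned to the population under selection.

hapFLK applies the same quadratic form to local haplotype-cluster
frequencies from a fastPHASE-style hidden Markov model, summing over
clusters and averaging over independent EM fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._hapclust import estep
from .io_formats import GenotypeMatrix, HET, MISSING
from .popstats import KinshipMatrix

logger = logging.getLogger(__name__)

_CLIP = 1e-6


# ---------------------------------------------------------------------------
# eigensystem of the kinship matrix
# ---------------------------------------------------------------------------


@dataclass
class EigenSystem:
    """F = Q' D Q with rows of Q the eigenvectors (descending eigenvalue)."""

    Q: np.ndarray
    D: np.ndarray  # eigenvalues, shape (npop,)
    populations: list[str]

    def __post_init__(self):
        npop = len(self.populations)
        if self.Q.shape != (npop, npop) or self.D.shape != (npop,):
            raise ValueError("inconsistent eigensystem shapes")
        if not np.allclose(self.Q @ self.Q.T, np.eye(npop), atol=1e-8):
            raise ValueError("Q is not orthogonal")


def eigensystem(kinship: KinshipMatrix) -> EigenSystem:
    w, V = np.linalg.eigh(kinship.F)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if w.min() <= 1e-10:
        raise np.linalg.LinAlgError("kinship matrix is singular")
    Q = V.T.copy()
    # deterministic sign: largest-|loading| entry of each eigenvector positive
    for i in range(Q.shape[0]):
        j = np.argmax(np.abs(Q[i]))
        if Q[i, j] < 0:
            Q[i] = -Q[i]
    return EigenSystem(Q, w, list(kinship.populations))


# ---------------------------------------------------------------------------
# single-SNP FLK
# ---------------------------------------------------------------------------


def estimate_p0(p: np.ndarray, F: np.ndarray) -> float:
    """GLS estimate of the ancestral frequency, clipped away from 0 and 1."""
    p = np.asarray(p, float)
    Fi = np.linalg.inv(F)
    one = np.ones(len(p))
    p0 = float(one @ Fi @ p) / float(one @ Fi @ one)
    return float(np.clip(p0, _CLIP, 1 - _CLIP))


def flk_statistic(p: np.ndarray, F: np.ndarray):
    """FLK for one site: returns ``(T, u)`` with ``T = Σ u_i²``.

    A monomorphic site (estimated p0 at the clip bound) yields T = 0 and
    a zero u-vector.
    """
    p = np.asarray(p, float)
    F = np.asarray(F, float)
    p0 = estimate_p0(p, F)
    if p0 <= _CLIP or p0 >= 1 - _CLIP:
        return 0.0, np.zeros(len(p))
    ptil = (p - p0) / np.sqrt(p0 * (1 - p0))
    Fi = np.linalg.inv(F)
    T = float(ptil @ Fi @ ptil)
    w, V = np.linalg.eigh(F)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    Q = V.T.copy()
    for i in range(Q.shape[0]):
        j = np.argmax(np.abs(Q[i]))
        if Q[i, j] < 0:
            Q[i] = -Q[i]
    u = (Q @ ptil) / np.sqrt(w)
    return T, u


@dataclass
class FlkResult:
    """Per-site FLK scan: table (chrom, pos, p0, T, p_value) plus u-vectors."""

    table: pd.DataFrame
    u: np.ndarray  # (nsites, npop) eigen-contributions
    eigen: EigenSystem
    df: int  # chi-squared degrees of freedom used for p-values

    def __post_init__(self):
        T = self.table["T"].to_numpy()
        usq = (self.u ** 2).sum(axis=1)
        ok = ~self.table["flagged"].to_numpy()
        if np.abs(T[ok] - usq[ok]).max(initial=0.0) > 1e-8:
            raise AssertionError("eigen identity |T - sum u_i^2| violated")


def flk_scan(
    freqs: np.ndarray,
    kinship: KinshipMatrix,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> FlkResult:
    """Vectorised FLK over a (npop, nsites) frequency table.

    Sites with any missing population frequency, or monomorphic after p0
    estimation, are flagged and given T = 0.  P-values use the χ² with
    npop − 1 degrees of freedom (the ancestral frequency is estimated).
    """
    F = kinship.F
    p = np.asarray(freqs, float)
    npop, L = p.shape
    if npop != len(kinship.populations):
        raise ValueError("frequency table does not match kinship populations")
    es = eigensystem(kinship)
    Fi = np.linalg.inv(F)
    one = np.ones(npop)
    w = Fi @ one / (one @ Fi @ one)

    bad = np.isnan(p).any(axis=0)
    psafe = np.where(np.isnan(p), 0.5, p)
    p0 = np.clip(w @ psafe, _CLIP, 1 - _CLIP)
    mono = (p0 <= _CLIP) | (p0 >= 1 - _CLIP)
    flagged = bad | mono

    denom = np.sqrt(p0 * (1 - p0))
    ptil = (psafe - p0[None, :]) / denom[None, :]
    T = np.einsum("il,ij,jl->l", ptil, Fi, ptil)
    u = (es.Q @ ptil) / np.sqrt(es.D)[:, None]
    T[flagged] = 0.0
    u[:, flagged] = 0.0

    dof = npop - 1
    pval = stats.chi2.sf(T, dof)
    pval[flagged] = 1.0
    table = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else np.repeat("1", L),
            "pos": pos if pos is not None else np.arange(1, L + 1),
            "p0": p0,
            "T": T,
            "p_value": pval,
            "flagged": flagged,
        }
    )
    return FlkResult(table, u.T, es, dof)


def flk_scan_genotypes(gm: GenotypeMatrix, kinship: KinshipMatrix) -> FlkResult:
    """FLK from genotype calls (haploid het treated as missing)."""
    pops, freqs = gm.pop_frequencies(het_haploid="missing")
    order = [pops.index(p) for p in kinship.populations]
    return flk_scan(
        freqs[order],
        kinship,
        chrom=gm.sites["chrom"].to_numpy(),
        pos=gm.sites["pos"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# haplotype-cluster model
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeClusterModel:
    """One EM fit of the jump HMM (per-locus θ, α, per-interval ρ)."""

    K: int
    theta: np.ndarray  # (L, K) per-locus cluster allele frequencies
    alpha: np.ndarray  # (L, K) cluster weights / jump destinations
    rho: np.ndarray  # (L-1,) jump probabilities
    loglik_trace: list[float] = field(default_factory=list)
    seed: int = 0


def haplotypes_from_gm(gm: GenotypeMatrix) -> np.ndarray:
    """0/1 haplotype matrix with het/missing imputed to the site-major allele."""
    calls = gm.calls.copy()
    bad = (calls == HET) | (calls == MISSING)
    alt_major = (calls == 1).sum(axis=0) >= (calls == 0).sum(axis=0)
    fill = np.broadcast_to(alt_major.astype(np.int8), calls.shape)
    return np.where(bad, fill, calls).astype(np.int8)


def _em_fit(G, K, em_tol, max_iter, rng) -> HaplotypeClusterModel:
    n, L = G.shape
    freq = G.mean(axis=0)
    theta = np.clip(
        freq[:, None] + rng.uniform(-0.2, 0.2, size=(L, K)), 0.05, 0.95
    )
    alpha = rng.dirichlet(np.full(K, 5.0), size=L)
    rho = np.full(L - 1, 0.05) if L > 1 else np.empty(0)
    trace: list[float] = []
    gamma_dummy = np.empty((1, 1, 1))
    num = np.empty((L, K))
    den = np.empty((L, K))
    jc = np.empty((max(L - 1, 1), K))
    stay = np.empty(max(L - 1, 1))
    prev = -np.inf
    for _ in range(max_iter):
        num[:] = 0.0
        den[:] = 0.0
        jc[:] = 0.0
        stay[:] = 0.0
        ll = estep(G, theta, alpha, rho, num, den, jc, stay, gamma_dummy, False)
        trace.append(ll)
        # M-step
        theta = np.clip(num / np.maximum(den, 1e-12), 1e-5, 1 - 1e-5)
        alpha = alpha.copy()
        alpha[0] = den[0] / n
        if L > 1:
            jtot = jc.sum(axis=1)
            alpha[1:] = (jc + 1e-9) / (jtot[:, None] + K * 1e-9)
            rho = np.clip(1.0 - stay / n, 1e-5, 1 - 1e-5)
        if np.isfinite(prev) and (ll - prev) < em_tol * max(abs(prev), 1.0):
            break
        prev = ll
    return HaplotypeClusterModel(K, theta, alpha, rho, trace)


def fit_cluster_model(
    haplotypes: np.ndarray,
    K: int = 10,
    n_fits: int = 20,
    em_tol: float = 1e-5,
    max_iter: int = 200,
    seed: int = 0,
) -> list[HaplotypeClusterModel]:
    """Fit ``n_fits`` independently seeded EM restarts of the cluster HMM.

    Haploid 0/1 genotypes of one chromosome, no missing values (use
    :func:`haplotypes_from_gm` to impute beforehand).
    """
    G = np.ascontiguousarray(haplotypes, dtype=np.int8)
    if K < 2:
        raise ValueError("K must be >= 2")
    if ((G != 0) & (G != 1)).any():
        raise ValueError("haplotypes must be 0/1 with no missing values")
    n_distinct = len({bytes(row) for row in G})
    if K > n_distinct:
        logger.warning(
            "K=%d exceeds the %d distinct haplotypes observed", K, n_distinct
        )
    models = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_fits):
        rng = np.random.default_rng(child)
        m = _em_fit(G, K, em_tol, max_iter, rng)
        m.seed = int(child.generate_state(1)[0] % (2**31))
        models.append(m)
    return models


def cluster_posteriors(G: np.ndarray, model: HaplotypeClusterModel) -> np.ndarray:
    """Per-haplotype per-locus cluster membership posteriors (n, L, K)."""
    G = np.ascontiguousarray(G, dtype=np.int8)
    n, L = G.shape
    K = model.K
    gamma = np.empty((n, L, K))
    num = np.zeros((L, K))
    den = np.zeros((L, K))
    jc = np.zeros((max(L - 1, 1), K))
    stay = np.zeros(max(L - 1, 1))
    estep(G, model.theta, model.alpha, model.rho, num, den, jc, stay, gamma, True)
    return gamma


# ---------------------------------------------------------------------------
# hapFLK
# ---------------------------------------------------------------------------


def hapflk_statistic(
    models: list[HaplotypeClusterModel],
    haplotypes: np.ndarray,
    pop_labels: np.ndarray,
    kinship: KinshipMatrix,
) -> np.ndarray:
    """Per-locus hapFLK: FLK quadratic form summed over haplotype clusters.

    For each EM fit, per-population cluster frequencies are the mean
    posterior memberships of that population's haplotypes; each cluster's
    frequency vector enters the FLK form with its own estimated ancestral
    frequency, the forms are summed over clusters, and the result is
    averaged over fits.
    """
    pop_labels = np.asarray(pop_labels)
    pops = kinship.populations
    groups = [np.flatnonzero(pop_labels == p) for p in pops]
    for p, g in zip(pops, groups):
        if g.size < 2:
            raise ValueError(f"population {p} has fewer than 2 haplotypes")
    F = kinship.F
    npop = len(pops)
    Fi = np.linalg.inv(F)
    one = np.ones(npop)
    w = Fi @ one / (one @ Fi @ one)

    L = haplotypes.shape[1]
    acc = np.zeros(L)
    for model in models:
        gamma = cluster_posteriors(haplotypes, model)
        # P[l, pop, k]: cluster frequencies per population
        P = np.stack([gamma[g].mean(axis=0) for g in groups], axis=1)
        p0 = np.einsum("p,lpk->lk", w, P)
        ok = (p0 > _CLIP) & (p0 < 1 - _CLIP)
        p0c = np.clip(p0, _CLIP, 1 - _CLIP)
        ptil = (P - p0c[:, None, :]) / np.sqrt(p0c * (1 - p0c))[:, None, :]
        Tlk = np.einsum("lik,ij,ljk->lk", ptil, Fi, ptil)
        acc += np.where(ok, Tlk, 0.0).sum(axis=1)
    return acc / len(models)


# ---------------------------------------------------------------------------
# p-value calibration from the empirical chi-squared density
# ---------------------------------------------------------------------------


def pvalues_from_chi2(values: np.ndarray, trim: float = 0.95):
    """Fit a scaled χ² to the genome-wide statistic and return p-values.

    A scale ``a`` and degrees of freedom ``d`` are estimated from the
    lower ``trim`` fraction of the distribution (robust to selected
    outliers) by matching the first two moments of the correspondingly
    truncated scaled-χ² density; p-values are the χ²_d upper tail of
    value / a.  Returns ``(pvalues, a, d)``.
    """
    from scipy.optimize import least_squares

    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 1000:
        logger.warning("pvalues_from_chi2: only %d loci; calibration unstable", v.size)
    if v.size < 3 or np.var(v) <= 1e-12 * max(np.mean(v) ** 2, 1.0):
        raise ValueError("cannot calibrate chi-squared: (near-)constant input")
    t = float(np.quantile(v, trim))
    sample = v[v <= t]
    m1 = sample.mean()
    m2 = (sample ** 2).mean()
    # init from untrimmed moments: mean = a d, var = 2 a^2 d
    mean_all, var_all = v.mean(), v.var()
    a0 = max(var_all / (2 * mean_all), 1e-6)
    d0 = max(2 * mean_all ** 2 / var_all, 0.1)

    def resid(log_params):
        a, d = np.exp(log_params)
        tau = t / a
        Z = stats.chi2.cdf(tau, d)
        if Z <= 1e-12:
            return np.array([1e6, 1e6])
        tm1 = a * d * stats.chi2.cdf(tau, d + 2) / Z
        tm2 = a**2 * d * (d + 2) * stats.chi2.cdf(tau, d + 4) / Z
        return np.array([tm1 / m1 - 1.0, tm2 / m2 - 1.0])

    sol = least_squares(resid, np.log([a0, d0]), xtol=1e-12, ftol=1e-12)
    a, d = np.exp(sol.x)
    pvals = stats.chi2.sf(np.asarray(values, float) / a, d)
    return pvals, float(a), float(d)


# ---------------------------------------------------------------------------
# region calling and population assignment
# ---------------------------------------------------------------------------


@dataclass
class SelectionRegion:
    """A genomic interval of significant hapFLK signal (flanks included)."""

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_p: float
    n_snps: int = 0
    measures: np.ndarray | None = None  # per-eigenvector selection measure
    assigned_population: str | None = None
    ambiguous: bool = False

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("end < start")


def call_regions(
    chrom: np.ndarray,
    pos: np.ndarray,
    pvalues: np.ndarray,
    alpha: float = 1e-4,
    chain_bp: int = 2000,
    flank_bp: int = 10_000,
) -> list[SelectionRegion]:
    """Chain significant positions into regions and extend flanks.

    Positions with p ≤ alpha are chained while consecutive gaps are
    ≤ ``chain_bp``; each chain becomes [min − flank, max + flank] clipped
    at 1; overlapping extended regions are merged (regions in the output
    are pairwise disjoint per chromosome).
    """
    chrom = np.asarray(chrom).astype(str)
    pos = np.asarray(pos, dtype=int)
    pvalues = np.asarray(pvalues, float)
    regions: list[SelectionRegion] = []
    for c in dict.fromkeys(chrom):
        m = (chrom == c) & (pvalues <= alpha)
        cpos = pos[m]
        cp = pvalues[m]
        if cpos.size == 0:
            continue
        order = np.argsort(cpos)
        cpos, cp = cpos[order], cp[order]
        chains = []
        s = e = 0
        for i in range(1, cpos.size):
            if cpos[i] - cpos[e] <= chain_bp:
                e = i
            else:
                chains.append((s, e))
                s = e = i
        chains.append((s, e))
        raw = []
        for s, e in chains:
            seg = slice(s, e + 1)
            ipk = s + int(np.argmin(cp[seg]))
            raw.append(
                [
                    max(1, int(cpos[s]) - flank_bp),
                    int(cpos[e]) + flank_bp,
                    int(cpos[ipk]),
                    float(cp[ipk]),
                ]
            )
        merged = [raw[0]]
        for r in raw[1:]:
            last = merged[-1]
            if r[0] <= last[1]:
                last[1] = max(last[1], r[1])
                if r[3] < last[3]:
                    last[2], last[3] = r[2], r[3]
            else:
                merged.append(r)
        for start, end, pk, pkp in merged:
            regions.append(SelectionRegion(c, start, end, pk, pkp))
    return regions


def assign_populations(
    regions: list[SelectionRegion],
    flk_result: FlkResult,
    percentile: float = 99.0,
    ratio: float = 2.0,
) -> list[SelectionRegion]:
    """Attach per-eigenvector selection measures and assign populations.

    For eigenvector i, the measure m_i sums the squared contributions u_i²
    of region SNPs exceeding the genome-wide ``percentile`` of u_i² and
    divides by the number of SNPs in the region.  The region is assigned
    to the population with the largest |loading| on the winning
    eigenvector only if its measure is at least ``ratio`` times every
    other eigenvector's; ties in the loading are reported as ambiguous.
    """
    es = flk_result.eigen
    ok = ~flk_result.table["flagged"].to_numpy()
    usq = flk_result.u ** 2  # (nsites, npop)
    thresh = np.percentile(usq[ok], percentile, axis=0)
    chrom = flk_result.table["chrom"].to_numpy().astype(str)
    pos = flk_result.table["pos"].to_numpy()
    out = []
    for reg in regions:
        inreg = (chrom == str(reg.chrom)) & (pos >= reg.start) & (pos <= reg.end)
        n_snps = int(inreg.sum())
        if n_snps == 0:
            out.append(reg)
            continue
        ru = usq[inreg]
        m = np.where(ru > thresh[None, :], ru, 0.0).sum(axis=0) / n_snps
        order = np.argsort(m)[::-1]
        istar = int(order[0])
        second = m[order[1]] if len(m) > 1 else 0.0
        assigned = None
        ambiguous = False
        if m[istar] > 0 and m[istar] >= ratio * second:
            loads = np.abs(es.Q[istar])
            best = loads.max()
            tied = np.flatnonzero(loads >= best - 1e-12)
            if len(tied) > 1:
                assigned = ",".join(es.populations[j] for j in tied)
                ambiguous = True
            else:
                assigned = es.populations[int(tied[0])]
        out.append(
            SelectionRegion(
                reg.chrom,
                reg.start,
                reg.end,
                reg.peak_pos,
                reg.peak_p,
                n_snps,
                m,
                assigned,
                ambiguous,
            )
        )
    return out
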