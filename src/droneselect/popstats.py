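"""Population statistics: windowed π, Reynolds distances, kinship, depth curve.

The kinship matrix F ties the whole selection scan together: it is built
by neighbor-joining a tree on −ln(1 − D) transformed pairwise Reynolds
distances, rooting on the outgroup branch, and reading off shared
root-to-leaf path lengths — the co-ancestry structure the FLK model
assumes under pure drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# windowed nucleotide diversity
# ---------------------------------------------------------------------------


def windowed_pi(
    gm: GenotypeMatrix, window: int = 5000, step: int = 1000, population: str | None = None
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity for one haploid population.

    Per-site diversity is the unbiased pairwise heterozygosity
    ``n/(n-1) * 2 p (1-p)`` over the ``n`` non-missing haploid calls; the
    window value divides the sum of contained sites by the window length
    in bp (so π is on the per-bp scale, ~0.002–0.006 for honeybees).
    Sites with fewer than two calls contribute zero (counted in a warning).
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    idx = None if population is None else gm.samples.indices_of(population)
    calls = gm.calls if idx is None else gm.calls[idx]
    ploidy = gm.samples.ploidy if idx is None else gm.samples.ploidy[idx]
    if not (ploidy == 1).all():
        raise ValueError("windowed_pi expects haploid samples")
    # haploid: het treated as missing (a haploid call is a single allele)
    valid = (calls == 0) | (calls == 1)
    n = valid.sum(axis=0)
    alt = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        h = np.where(n >= 2, n / np.maximum(n - 1, 1) * 2 * p * (1 - p), 0.0)
    n_low = int((n < 2).sum())
    if n_low:
        logger.warning("windowed_pi: %d sites with <2 calls contribute 0", n_low)

    rows = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        hv = h[grp.index.to_numpy()]
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window - 1
            inwin = (pos >= start) & (pos <= end)
            rows.append((chrom, start, end, hv[inwin].sum() / window))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "win_start", "win_end", "pi"])


def genome_pi(pi_table: pd.DataFrame) -> float:
    """Genome-wide π: unweighted mean over windows."""
    return float(pi_table["pi"].mean())


# ---------------------------------------------------------------------------
# Reynolds distance and kinship
# ---------------------------------------------------------------------------


def reynolds_distance(freqs: np.ndarray, i: int, j: int) -> float:
    """Multilocus Reynolds distance between populations i and j.

    Ratio-of-sums estimator over loci ``l``:
    ``D = Σ (p_i − p_j)² / Σ (1 − p_i p_j − (1−p_i)(1−p_j))``.
    """
    pi_, pj = np.asarray(freqs[i], float), np.asarray(freqs[j], float)
    ok = ~(np.isnan(pi_) | np.isnan(pj))
    pi_, pj = pi_[ok], pj[ok]
    if pi_.size == 0:
        raise ValueError("no informative sites")
    num = np.sum((pi_ - pj) ** 2)
    den = np.sum(1 - pi_ * pj - (1 - pi_) * (1 - pj))
    if den <= 0:
        logger.warning("reynolds_distance: zero denominator (all sites fixed)")
        return 0.0
    return float(num / den)


def reynolds_matrix(freqs: np.ndarray) -> np.ndarray:
    npop = freqs.shape[0]
    D = np.zeros((npop, npop))
    for i in range(npop):
        for j in range(i + 1, npop):
            D[i, j] = D[j, i] = reynolds_distance(freqs, i, j)
    return D


@dataclass
class KinshipMatrix:
    """Co-ancestry matrix F over the ingroup populations (outgroup removed)."""

    populations: list[str]
    F: np.ndarray

    def __post_init__(self):
        self.F = np.asarray(self.F, float)
        if self.F.shape != (len(self.populations),) * 2:
            raise ValueError("F shape does not match population labels")
        if not np.allclose(self.F, self.F.T, atol=1e-8):
            raise ValueError("F must be symmetric")
        if (np.diag(self.F) <= 0).any():
            raise ValueError("F diagonal must be positive")
        if np.linalg.eigvalsh(self.F).min() < -1e-8:
            raise ValueError("F must be positive semi-definite")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.F, index=self.populations, columns=self.populations).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy())


def kinship_from_distances(
    distance_matrix: np.ndarray, labels: list[str], outgroup_label: str
) -> KinshipMatrix:
    """Build F from pairwise distances via a neighbor-joining tree.

    Distances are transformed ``t = −ln(1 − D)`` (additive under drift),
    a NJ tree is built, negative branch lengths are clamped to zero, the
    tree is rooted on the outgroup branch, and ``F_ij`` is the shared
    root-to-leaf path length of populations i and j (``F_ii`` the full
    root-to-leaf length).  The outgroup is removed from the result.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.asarray(distance_matrix, float)
    if outgroup_label not in labels:
        raise ValueError(f"outgroup {outgroup_label!r} not among labels {labels}")
    if len(labels) < 3:
        raise ValueError("need at least 3 populations including the outgroup")
    if (D >= 1).any():
        raise ValueError("Reynolds distances must be < 1 for the log transform")
    T = -np.log(1 - D)
    np.fill_diagonal(T, 0.0)
    tree = nj(DistanceMatrix(T, ids=list(labels)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0

    # root-to-leaf paths measured from the node where the outgroup attaches:
    # rooting anywhere on the outgroup branch yields the same ingroup paths.
    og = tree.find(outgroup_label)
    pend = og.length or 0.0
    ingroup = [l for l in labels if l != outgroup_label]
    d = {}
    for a in labels:
        for b in labels:
            if a < b:
                d[(a, b)] = d[(b, a)] = tree.find(a).distance(tree.find(b))
    npop = len(ingroup)
    F = np.zeros((npop, npop))
    for i, a in enumerate(ingroup):
        F[i, i] = d[(outgroup_label, a)] - pend
        for j in range(i + 1, npop):
            b = ingroup[j]
            shared = (
                d[(outgroup_label, a)] + d[(outgroup_label, b)] - d[(a, b)]
            ) / 2 - pend
            F[i, j] = F[j, i] = max(shared, 0.0)
    return KinshipMatrix(ingroup, F)


def kinship_from_genotypes(gm: GenotypeMatrix, outgroup: str) -> KinshipMatrix:
    """Reynolds distances → NJ tree → kinship, from genotype calls."""
    pops, freqs = gm.pop_frequencies(het_haploid="missing")
    D = reynolds_matrix(freqs)
    return kinship_from_distances(D, pops, outgroup)


# ---------------------------------------------------------------------------
# depth / callable-fraction calibration
# ---------------------------------------------------------------------------


@dataclass
class DepthCurve:
    """Saturating-exponential fit GX = a (1 − exp(−DP / b))."""

    a: float
    b: float
    points: np.ndarray  # (n, 2) of (DP, GX)

    def __post_init__(self):
        if not (0 < self.a <= 1):
            raise ValueError("asymptote a must be in (0, 1]")
        if self.b <= 0:
            raise ValueError("rate b must be > 0")

    def predict(self, dp: np.ndarray) -> np.ndarray:
        return self.a * (1 - np.exp(-np.asarray(dp, float) / self.b))


def fit_depth_curve(points) -> DepthCurve:
    """Least-squares fit of callable fraction against mean depth."""
    from scipy.optimize import curve_fit

    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (DP, GX) points")
    dp, gx = pts[:, 0], pts[:, 1]
    if ((gx <= 0) | (gx >= 1)).any():
        raise ValueError("GX values must be in (0, 1)")
    if np.allclose(dp, dp[0]):
        raise ValueError("degenerate fit: all DP values identical")

    def f(x, a, b):
        return a * (1 - np.exp(-x / b))

    try:
        (a, b), _ = curve_fit(
            f, dp, gx, p0=[min(0.99, gx.max() * 1.05), max(dp.mean(), 1e-3)],
            bounds=([1e-6, 1e-6], [1.0, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"depth-curve fit did not converge: {exc}") from exc
    resid = gx - f(dp, a, b)
    if np.abs(resid).max() > 0.2:
        raise RuntimeError(
            f"depth-curve fit poorly converged (max residual {np.abs(resid).max():.3f})"
        )
    return DepthCurve(float(a), float(b), pts)


def invert_depth_curve(curve: DepthCurve, gx_target: float) -> float:
    """Depth needed for a target callable fraction: DP = −b ln(1 − GX/a)."""
    if gx_target >= curve.a:
        raise ValueError(
            f"target GX {gx_target} is at/above the fitted asymptote {curve.a:.4f}"
        )
    if gx_target <= 0:
        raise ValueError("gx_target must be positive")
    return float(-curve.b * np.log(1 - gx_target / curve.a))
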