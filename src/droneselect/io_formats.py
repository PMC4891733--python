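"""Standard-format I/O and the genotype-matrix container.

The pipeline works from VCF genotype calls of haploid drones (optionally
diploid workers), a tab-separated sample table assigning each sample to a
population, BED interval annotations and GFF3 gene models.  Everything is
converted at the boundary to a single in-memory representation:

* coordinates are 1-based inclusive everywhere inside the package (the
  VCF/GFF convention); BED's half-open 0-based intervals are converted on
  read and write;
* genotype calls are small integers (``REF``/``ALT``/``HET``/``MISSING``);
  heterozygous calls in haploid samples are *retained* because the CNV
  scan consumes them, while frequency-based analyses treat them as missing.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype call codes
REF: int = 0
ALT: int = 1
HET: int = 2
MISSING: int = -1


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _chrom_key(chrom: str):
    """Sort key placing numeric chromosome names in numeric order."""
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Sample → population assignment with ploidy (1 for drones, 2 for workers)."""

    df: pd.DataFrame

    def __post_init__(self):
        required = {"sample_id", "population", "ploidy"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        ids = self.df["sample_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        if (self.df["population"].astype(str).str.len() == 0).any():
            raise ValueError("empty population label")
        if not self.df["ploidy"].isin([1, 2]).all():
            raise ValueError("ploidy must be 1 or 2")

    @classmethod
    def from_records(
        cls, sample_ids: Sequence[str], populations: Sequence[str], ploidy=1
    ) -> "SampleTable":
        n = len(sample_ids)
        pl = [ploidy] * n if np.isscalar(ploidy) else list(ploidy)
        return cls(
            pd.DataFrame(
                {
                    "sample_id": list(map(str, sample_ids)),
                    "population": list(map(str, populations)),
                    "ploidy": pl,
                }
            )
        )

    @classmethod
    def from_tsv(cls, path) -> "SampleTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
        return cls(df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def populations(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        return list(dict.fromkeys(self.df["population"]))

    @property
    def ploidy(self) -> np.ndarray:
        return self.df["ploidy"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.df)

    def indices_of(self, population: str) -> np.ndarray:
        return np.flatnonzero((self.df["population"] == population).to_numpy())

    def subset(self, idx) -> "SampleTable":
        return SampleTable(self.df.iloc[np.asarray(idx)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples × biallelic-SNP matrix of calls and per-call depth.

    ``sites`` holds columns ``chrom, pos, ref, alt`` sorted by (chrom, pos);
    ``calls`` and ``depth`` are (n_samples, n_sites) arrays aligned to it.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray
    samples: SampleTable

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        ns, nl = self.samples.n, len(self.sites)
        if self.calls.shape != (ns, nl) or self.depth.shape != (ns, nl):
            raise ValueError(
                f"shape mismatch: calls {self.calls.shape}, depth {self.depth.shape},"
                f" expected {(ns, nl)}"
            )
        if (self.depth < 0).any():
            raise ValueError("negative depth")
        keys = list(
            zip(map(_chrom_key, self.sites["chrom"]), self.sites["pos"])
        )
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("sites must be sorted by (chrom, pos) and unique")

    # -- basic properties ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.n

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            self.sites.iloc[idx], self.calls[:, idx], self.depth[:, idx], self.samples
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.sites, self.calls[idx], self.depth[idx], self.samples.subset(idx)
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.depth, other.depth)
            and self.samples.df.reset_index(drop=True).equals(
                other.samples.df.reset_index(drop=True)
            )
        )

    # -- allele counting ----------------------------------------------------

    def allele_counts(self, sample_idx=None, het_haploid: str = "allele"):
        """Per-site (alt_copies, total_copies) over the given samples.

        ``het_haploid`` controls heterozygous calls in haploid samples:
        ``"allele"`` counts one copy of each allele (the MAF convention),
        ``"missing"`` drops them (the FLK convention, where a haploid site
        is a single 0/1 allele).
        Diploid calls always contribute two allele copies.
        """
        if het_haploid not in ("allele", "missing"):
            raise ValueError("het_haploid must be 'allele' or 'missing'")
        idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        calls = self.calls[idx]
        ploidy = self.samples.ploidy[idx][:, None]
        tot = np.where(calls == MISSING, 0, ploidy)
        alt = np.where(calls == ALT, ploidy, 0)
        is_het = calls == HET
        # het: one alt copy; haploid het counts 2 copies in "allele" mode
        alt = alt + np.where(is_het, 1, 0)
        if het_haploid == "allele":
            tot = tot + np.where(is_het & (ploidy == 1), 1, 0)
        else:
            drop = is_het & (ploidy == 1)
            tot = np.where(drop, 0, tot)
            alt = np.where(drop, 0, alt)
        return alt.sum(axis=0), tot.sum(axis=0)

    def frequencies(self, sample_idx=None, het_haploid: str = "allele") -> np.ndarray:
        alt, tot = self.allele_counts(sample_idx, het_haploid)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def pop_frequencies(self, het_haploid: str = "missing"):
        """(population labels, npop × nsites alt-allele frequency table)."""
        pops = self.samples.populations
        freq = np.vstack(
            [self.frequencies(self.samples.indices_of(p), het_haploid) for p in pops]
        )
        return pops, freq


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path, sample_table: SampleTable) -> GenotypeMatrix:
    """Read a VCF 4.x of biallelic SNPs into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped with a logged warning.
    Haploid GT "0"/"1" map to ref/alt, "0/1" to het, "." to missing; DP is
    taken from the per-genotype FORMAT field (absent → 0).
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise FormatError(f"{path}: no GT FORMAT field declared")
    vcf_samples = list(vf.header.samples)
    unknown = [s for s in vcf_samples if s not in set(sample_table.sample_ids)]
    if unknown:
        raise ValueError(f"samples in VCF absent from sample table: {unknown}")
    absent = [s for s in sample_table.sample_ids if s not in set(vcf_samples)]
    if absent:
        raise ValueError(f"samples in table absent from VCF: {absent}")

    order = [vcf_samples.index(s) for s in sample_table.sample_ids]
    rows, calls, depths = [], [], []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        ccol = np.empty(len(vcf_samples), dtype=np.int8)
        dcol = np.zeros(len(vcf_samples), dtype=np.int32)
        for i, s in enumerate(vcf_samples):
            sd = rec.samples[s]
            gt = sd.get("GT")
            if gt is None or len(gt) == 0 or all(a is None for a in gt):
                ccol[i] = MISSING
            else:
                alleles = {a for a in gt if a is not None}
                if None in set(gt) or len(gt) != len([a for a in gt if a is not None]):
                    ccol[i] = MISSING
                elif alleles == {0}:
                    ccol[i] = REF
                elif alleles == {1}:
                    ccol[i] = ALT
                elif alleles == {0, 1}:
                    ccol[i] = HET
                else:
                    ccol[i] = MISSING
            dp = sd.get("DP")
            dcol[i] = 0 if dp is None else int(dp)
        rows.append((str(rec.chrom), int(rec.pos), rec.ref, alts[0]))
        calls.append(ccol[order])
        depths.append(dcol[order])
    if n_skipped:
        logger.warning("%s: skipped %d multi-allelic/non-SNP records", path, n_skipped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    calls_arr = (
        np.array(calls, dtype=np.int8).T if calls else np.empty((sample_table.n, 0), np.int8)
    )
    depth_arr = (
        np.array(depths, dtype=np.int32).T
        if depths
        else np.empty((sample_table.n, 0), np.int32)
    )
    return GenotypeMatrix(sites, calls_arr, depth_arr, sample_table)


_GT_STR = {REF: "0", ALT: "1", HET: "0/1", MISSING: "."}
_GT_STR_DIP = {REF: "0/0", ALT: "1/1", HET: "0/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT:DP) round-trippable by :func:`read_vcf`."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples.sample_ids)
            + "\n"
        )
        ploidy = gm.samples.ploidy
        for j in range(gm.n_sites):
            site = gm.sites.iloc[j]
            cols = [
                str(site["chrom"]),
                str(int(site["pos"])),
                ".",
                site["ref"],
                site["alt"],
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for i in range(gm.n_samples):
                table = _GT_STR_DIP if ploidy[i] == 2 else _GT_STR
                cols.append(f"{table[int(gm.calls[i, j])]}:{int(gm.depth[i, j])}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# site filtering and in-silico diploids
# ---------------------------------------------------------------------------


def filter_sites(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.9,
    chroms: set | None = None,
) -> GenotypeMatrix:
    """Retain sites by chromosome, minor allele frequency and call rate.

    MAF is computed over non-missing allele copies with heterozygous calls
    contributing one copy of each allele; call rate is the fraction of
    samples with a non-missing genotype.  Both thresholds are inclusive.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 < call_rate_min <= 1):
        raise ValueError("call_rate_min must be in (0, 1]")
    alt, tot = gm.allele_counts(het_haploid="allele")
    with np.errstate(invalid="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    call_rate = (gm.calls != MISSING).sum(axis=0) / gm.n_samples
    keep = (maf >= maf_min - 1e-12) & (call_rate >= call_rate_min - 1e-12) & (tot > 0)
    if chroms is not None:
        chroms = {str(c) for c in chroms}
        keep &= gm.sites["chrom"].astype(str).isin(chroms).to_numpy()
    if not keep.any():
        logger.warning("filter_sites: no site survived the filters")
    return gm.subset_sites(keep)


_DIPLOID_COMBINE = {
    (REF, REF): REF,
    (ALT, ALT): ALT,
    (REF, ALT): HET,
    (ALT, REF): HET,
}


def make_insilico_diploids(gm: GenotypeMatrix, pairing_seed: int) -> GenotypeMatrix:
    """Pair haploid drones within populations into in-silico diploids.

    Pairs are drawn without replacement with a seeded RNG; the diploid
    genotype is the multiset of the two haploid alleles and depth the sum
    of depths.  Haploid het or missing calls propagate as missing.  An odd
    drone per population is dropped with a warning; populations with fewer
    than two drones are skipped.
    """
    if not (gm.samples.ploidy == 1).all():
        raise ValueError("make_insilico_diploids requires all-haploid input")
    rng = np.random.default_rng(pairing_seed)
    new_ids, new_pops, rows_calls, rows_depth = [], [], [], []
    for pop in gm.samples.populations:
        idx = gm.samples.indices_of(pop)
        if len(idx) < 2:
            logger.warning("population %s has <2 drones; skipped", pop)
            continue
        perm = rng.permutation(idx)
        if len(perm) % 2:
            logger.warning(
                "population %s: odd drone count, dropping %s",
                pop,
                gm.samples.sample_ids[perm[-1]],
            )
            perm = perm[:-1]
        for a, b in perm.reshape(-1, 2):
            ca, cb = gm.calls[a], gm.calls[b]
            combined = np.full_like(ca, MISSING)
            for (x, y), z in _DIPLOID_COMBINE.items():
                combined[(ca == x) & (cb == y)] = z
            rows_calls.append(combined)
            rows_depth.append(gm.depth[a] + gm.depth[b])
            ids = gm.samples.sample_ids
            new_ids.append(f"{ids[a]}x{ids[b]}")
            new_pops.append(pop)
    table = SampleTable.from_records(new_ids, new_pops, ploidy=2)
    return GenotypeMatrix(
        gm.sites,
        np.array(rows_calls, dtype=np.int8),
        np.array(rows_depth, dtype=np.int32),
        table,
    )


# ---------------------------------------------------------------------------
# intervals: BED and GFF3
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 1-based inclusive (the internal convention)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"end < start in {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval", margin: int = 0) -> bool:
        return (
            self.chrom == other.chrom
            and self.start - margin <= other.end
            and other.start <= self.end + margin
        )


def read_bed(path) -> list[Interval]:
    """Read BED3+ (0-based half-open) into 1-based inclusive intervals."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end0 <= start0:
                raise FormatError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else ""
            out.append(Interval(parts[0], start0 + 1, end0, name))
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if iv.name:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


def read_gff3_genes(path) -> list[Interval]:
    """Extract gene features from a GFF3 file as 1-based inclusive intervals."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for gene in db.features_of_type("gene"):
        name = gene.id or (gene.attributes.get("Name", [""])[0])
        out.append(Interval(gene.seqid, gene.start, gene.end, name))
    return sorted(out, key=lambda iv: (_chrom_key(iv.chrom), iv.start))
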