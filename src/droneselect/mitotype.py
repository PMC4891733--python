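"""Mitotype reconstruction from WGS reads against a reference panel.

The mitochondrial tRNA\\ :sup:`Leu`–cox2 intergenic region characterises
honeybee mitotypes through point mutations/indels in the P element and
the tandem copy number of the Q element.  Reads spanning the region are
aligned to every panel reference; each reference receives an error rate
``e`` (high-quality mismatch rate plus indel rate) and an alignment
quality ``q`` (fraction of aligned bases that are high-quality with base
quality ≥ Q20).  References with ``e > 0`` and ``q > 0.5`` are acceptable;
the best match has the lowest ``e`` (6-decimal precision), breaking ties
by the longest sequence.  The ``e > 0`` rule deliberately rejects perfect
alignments, which would otherwise favour very short references.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .synthetic_data import ANCHOR_3, ANCHOR_5, FastqRead

logger = logging.getLogger(__name__)


class AnchorError(ValueError):
    """An anchor motif is missing or duplicated."""


# ---------------------------------------------------------------------------
# panel handling
# ---------------------------------------------------------------------------


def trim_to_anchors(
    raw: str, anchor5: str = ANCHOR_5, anchor3: str = ANCHOR_3
) -> str:
    """Subsequence strictly between the tRNA-Leu and COX2 anchor motifs.

    Both motifs must occur exactly once (case-insensitive); re-trimming an
    already trimmed sequence therefore raises, guarding double trims.
    """
    up = raw.upper()
    for name, motif in (("5' anchor", anchor5), ("3' anchor", anchor3)):
        n = up.count(motif.upper())
        if n == 0:
            raise AnchorError(f"{name} motif {motif!r} not found")
        if n > 1:
            raise AnchorError(f"{name} motif {motif!r} occurs {n} times")
    i5 = up.index(anchor5.upper()) + len(anchor5)
    i3 = up.index(anchor3.upper())
    if i3 < i5:
        raise AnchorError("anchors out of order")
    return raw[i5:i3]


@dataclass
class MitotypePanel:
    """Reference mitotypes trimmed to the inter-anchor region."""

    entries: list[tuple[str, str]]  # (accession, trimmed sequence)

    def __post_init__(self):
        accs = [a for a, _ in self.entries]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in panel")
        if any(not s for _, s in self.entries):
            raise ValueError("empty panel sequence")

    @classmethod
    def from_raw(cls, raw_entries) -> "MitotypePanel":
        return cls([(acc, trim_to_anchors(seq)) for acc, seq in raw_entries])

    @classmethod
    def from_fasta(cls, path, trim: bool = True) -> "MitotypePanel":
        from Bio import SeqIO

        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq)
            entries.append((rec.id, trim_to_anchors(seq) if trim else seq))
        return cls(entries)


# ---------------------------------------------------------------------------
# read recovery
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_region(region: str):
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region {region!r} (expected chrom:start-end)")
    return m["chrom"], int(m["start"]), int(m["end"])


def extract_region_reads(sam_path, region: str) -> list[FastqRead]:
    """Reads overlapping the region by ≥ 1 bp, as FASTQ records.

    ``sam_path`` is a SAM/BAM alignment; mates are not required to map.
    """
    import pysam

    chrom, start, end = parse_region(region)
    out = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.reference_name != chrom:
                continue
            # reference_start is 0-based; convert to 1-based inclusive
            rstart = rec.reference_start + 1
            rend = rec.reference_end  # 1-based inclusive end
            if rend is None or rend < start or rstart > end:
                continue
            qual = (
                np.array(rec.query_qualities, dtype=int)
                if rec.query_qualities is not None
                else np.full(len(rec.query_sequence or ""), 30, dtype=int)
            )
            out.append(FastqRead(rec.query_name, rec.query_sequence or "", qual))
    if not out:
        raise ValueError(f"no informative reads in {region}")
    return out


def read_fastq(path) -> list[FastqRead]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            FastqRead(
                rec.id,
                str(rec.seq),
                np.array(rec.letter_annotations["phred_quality"], dtype=int),
            )
        )
    return out


# ---------------------------------------------------------------------------
# alignment scoring
# ---------------------------------------------------------------------------


@dataclass
class MitotypeMatch:
    accession: str
    e: float  # error rate, compared at 6-decimal precision
    q: float  # fraction of aligned bases that are HQ with BQ >= 20
    length: int
    accepted: bool

    @property
    def e6(self) -> float:
        return round(self.e, 6)


def _make_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(aln, read: FastqRead):
    """(aligned_bases, mismatches, indel_events, q20_bases) of one alignment."""
    tpos, qpos = aln.aligned  # blocks in target (reference) and query (read)
    target = str(aln.target)
    query = str(aln.query)
    aligned = mism = q20 = 0
    indels = max(len(tpos) - 1, 0) if len(tpos) else 0
    for (ts, te), (qs, qe) in zip(tpos, qpos):
        aligned += te - ts
        tseq = target[ts:te]
        qseq = query[qs:qe]
        mism += sum(1 for a, b in zip(tseq, qseq) if a != b)
        q20 += int((read.qual[qs:qe] >= 20).sum())
    return aligned, mism, indels, q20


def score_against_panel(
    reads: list[FastqRead],
    panel: MitotypePanel,
    hq_min_identity: float = 0.95,
    hq_min_aligned: int = 30,
) -> list[MitotypeMatch]:
    """Score every panel reference against the read set.

    A read's alignment is high-quality (HQ) when its identity over aligned
    bases is ≥ ``hq_min_identity`` with ≥ ``hq_min_aligned`` aligned bases
    (the mapping-quality ≥ 20 analogue).  Per reference:
    ``e`` = HQ mismatches / HQ aligned bases + HQ indel events / HQ aligned
    bases; ``q`` = HQ aligned bases with base quality ≥ 20 / all aligned
    bases.  Alignment is deterministic local affine (match +1, mismatch −2,
    gap open −4, extend −1).
    """
    if not panel.entries:
        raise ValueError("empty mitotype panel")
    if not reads:
        raise ValueError("no reads to score")
    aligner = _make_aligner()
    matches = []
    for acc, ref in panel.entries:
        tot_aligned = 0
        hq_aligned = hq_mism = hq_indels = hq_q20 = 0
        for read in reads:
            alns = aligner.align(ref, read.seq)
            if len(alns) == 0 or alns.score <= 0:
                continue
            aln = alns[0]  # deterministic first-in-order optimum
            aligned, mism, indels, q20 = _alignment_stats(aln, read)
            if aligned == 0:
                continue
            tot_aligned += aligned
            identity = 1 - mism / aligned
            if identity >= hq_min_identity and aligned >= hq_min_aligned:
                hq_aligned += aligned
                hq_mism += mism
                hq_indels += indels
                hq_q20 += q20
        if hq_aligned > 0:
            e = hq_mism / hq_aligned + hq_indels / hq_aligned
        else:
            e = float("inf")
        q = hq_q20 / tot_aligned if tot_aligned > 0 else 0.0
        accepted = np.isfinite(e) and e > 0 and q > 0.5
        matches.append(MitotypeMatch(acc, float(e), float(q), len(ref), accepted))
    return matches


def select_best(matches: list[MitotypeMatch]) -> MitotypeMatch:
    """Lowest error rate wins; ties go to the longest sequence.

    Error rates are compared at 6-decimal precision.  A residual tie is
    broken by the lexicographically smallest accession and logged as
    ambiguous.  Deterministic and invariant to input order.
    """
    accepted = [m for m in matches if m.accepted]
    if not accepted:
        raise ValueError("no acceptable mitotype (need e > 0 and q > 0.5)")
    best = sorted(accepted, key=lambda m: (m.e6, -m.length, m.accession))
    if (
        len(best) > 1
        and best[1].e6 == best[0].e6
        and best[1].length == best[0].length
    ):
        logger.warning(
            "ambiguous best mitotype: %s and %s tie on e and length",
            best[0].accession,
            best[1].accession,
        )
    return best[0]


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def consensus_sequence(reads: list[FastqRead], reference: str) -> str:
    """Majority-vote pileup consensus against the best reference.

    Reads are locally aligned to the reference; at each covered position
    the majority read base replaces the reference base (ties keep the
    reference base when it is among the tied, else the alphabetically
    first).  Uncovered positions keep the reference base; indels are not
    applied, so the output has the reference length.
    """
    aligner = _make_aligner()
    counts = np.zeros((len(reference), 4), dtype=int)
    for read in reads:
        alns = aligner.align(reference, read.seq)
        if len(alns) == 0 or alns.score <= 0:
            continue
        aln = alns[0]
        tpos, qpos = aln.aligned
        for (ts, te), (qs, qe) in zip(tpos, qpos):
            for off in range(te - ts):
                b = read.seq[qs + off]
                if b in _BASE_IDX:
                    counts[ts + off, _BASE_IDX[b]] += 1
    out = list(reference)
    bases = "ACGT"
    for i in range(len(reference)):
        tot = counts[i].sum()
        if tot == 0:
            continue
        mx = counts[i].max()
        tied = [bases[j] for j in range(4) if counts[i, j] == mx]
        if reference[i].upper() in tied:
            out[i] = reference[i]
        else:
            out[i] = tied[0]
    return "".join(out)


# ---------------------------------------------------------------------------
# network preparation
# ---------------------------------------------------------------------------


def recode_for_network(aligned_seqs: list[str]) -> list[str]:
    """Reduce to a 3-letter alphabet: recode C→G first, then gaps (−)→C.

    Keeps indel information (former gaps become the now-free letter C) so
    network software that masks gappy columns retains them.  Alignment
    dimensions are unchanged.
    """
    out = []
    for s in aligned_seqs:
        out.append(s.upper().replace("C", "G").replace("-", "C"))
    return out


def segregating_sites(
    aligned_seqs: list[str], missing_mask_fraction: float = 0.05
):
    """Count segregating columns after masking gappy/ambiguous columns.

    Columns whose gap/N fraction exceeds ``missing_mask_fraction`` are
    masked; remaining columns with ≥ 2 observed states are segregating.
    Returns ``(count, column_indices)``.
    """
    if not aligned_seqs:
        return 0, []
    L = len(aligned_seqs[0])
    if any(len(s) != L for s in aligned_seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")
    n = len(aligned_seqs)
    cols = []
    for j in range(L):
        column = [s[j].upper() for s in aligned_seqs]
        missing = sum(1 for c in column if c in "-N.")
        if missing / n > missing_mask_fraction:
            continue
        observed = {c for c in column if c not in "-N."}
        if len(observed) >= 2:
            cols.append(j)
    return len(cols), cols
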