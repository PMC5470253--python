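"""Amplicon indel calling from alignment cigars.

Insertions and deletions are read directly from the alignment cigar
records (substitutions never create indel rows), left-aligned against the
reference to the lowest compatible coordinate, and aggregated into a
per-allele table with frequencies relative to all reads.  Indel positions
are reported at the leftmost affected base, 1-based on the amplicon
reference; insertions are anchored at the last reference base before the
inserted sequence.  The Cas9 cut-site convention (blunt cut between
protospacer positions 17 and 18, i.e. 3 nt 5' of the PAM) is recorded in
the table metadata.

A naive gapped aligner is included as a convenience for raw FASTQ input,
with pinned scoring: match +2, mismatch -3, gap open -5, gap extend -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from Bio import Align

__all__ = [
    "IndelTable",
    "InsufficientDataError",
    "left_align_deletion",
    "left_align_insertion",
    "call_indels",
    "classify_sgrna",
    "correlate_editing_skipping",
    "align_reads",
    "CUT_SITE_CONVENTION",
]

CUT_SITE_CONVENTION = (
    "blunt cut between protospacer positions 17 and 18 (3 nt 5' of the PAM); "
    "cut position = last reference base 5' of the cleavage"
)


class InsufficientDataError(ValueError):
    """Fewer than three complete pairs for correlation."""


@dataclass
class IndelTable:
    """Aggregated indel spectrum at an amplicon target site.

    ``rows`` has columns (position, type, allele, count, frequency);
    frequency is count / n_reads.  ``edited_fraction`` is the fraction of
    reads carrying at least one indel in the target window.
    """

    target: tuple[str, Optional[int]]
    rows: pd.DataFrame
    n_reads: int
    n_edited: int
    metadata: dict = field(default_factory=dict)

    @property
    def edited_fraction(self) -> float:
        return self.n_edited / self.n_reads if self.n_reads else math.nan


def left_align_deletion(pos: int, seq: str, ref: str) -> tuple[int, str]:
    """Shift a deletion to its lowest compatible reference coordinate.

    The deletion removes ``seq`` at 1-based positions [pos, pos+len-1] of
    ``ref``; it may shift left one base whenever the base preceding it
    equals its last deleted base.  Idempotent once fully shifted.
    """
    d = len(seq)
    while pos > 1 and ref[pos - 2] == seq[-1]:
        seq = ref[pos - 2] + seq[:-1]
        pos -= 1
    return pos, seq


def left_align_insertion(anchor: int, seq: str, ref: str) -> tuple[int, str]:
    """Shift an insertion (anchored after 1-based ``anchor``) left.

    An insertion may rotate one base left whenever the reference base at
    the anchor equals the last inserted base.
    """
    while anchor >= 1 and ref[anchor - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        anchor -= 1
    return anchor, seq


def _read_indels(rec: pysam.AlignedSegment, ref: str) -> list[tuple[int, str, str]]:
    """(position, type, allele sequence) for each cigar indel, left-aligned."""
    out = []
    rpos = rec.reference_start  # 0-based
    qpos = 0
    query = rec.query_sequence or ""
    for op, ln in rec.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            rpos += ln
            qpos += ln
        elif op == 1:  # I
            ins = query[qpos : qpos + ln]
            anchor, seq = left_align_insertion(rpos, ins, ref)
            out.append((anchor, "ins", seq))
            qpos += ln
        elif op == 2:  # D
            dele = ref[rpos : rpos + ln]
            pos, seq = left_align_deletion(rpos + 1, dele, ref)
            out.append((pos, "del", seq))
            rpos += ln
        elif op == 3:  # N
            rpos += ln
        elif op == 4:  # S
            qpos += ln
    return out


def call_indels(
    alignments: Union[str, Path, Iterable[pysam.AlignedSegment]],
    ref_sequence: str,
    window: Optional[tuple[int, int]] = None,
    min_frequency: float = 0.005,
    target: Optional[tuple[str, int]] = None,
) -> IndelTable:
    """Aggregate cigar indels over amplicon alignments.

    ``window`` restricts calls to a 1-based inclusive reference interval
    (e.g. around the cut site).  Alleles below ``min_frequency`` (default
    0.5%, suppressing sequencing-error artifacts) are dropped from the
    table but still count toward ``edited_fraction``.
    """
    close_me = None
    if isinstance(alignments, (str, Path)):
        close_me = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        records: Iterable[pysam.AlignedSegment] = close_me
    else:
        records = alignments
    if window is not None and not (
        1 <= window[0] <= window[1] <= len(ref_sequence)
    ):
        raise ValueError("window outside reference")

    agg: dict[tuple[int, str, str], int] = {}
    n_reads = 0
    n_edited = 0
    try:
        for rec in records:
            if rec.is_unmapped:
                continue
            n_reads += 1
            hits = _read_indels(rec, ref_sequence)
            if window is not None:
                lo, hi = window
                hits = [h for h in hits if lo <= h[0] <= hi]
            if hits:
                n_edited += 1
            for h in hits:
                agg[h] = agg.get(h, 0) + 1
    finally:
        if close_me is not None:
            close_me.close()

    rows = [
        {
            "position": pos,
            "type": kind,
            "allele": allele,
            "count": c,
            "frequency": c / n_reads,
        }
        for (pos, kind, allele), c in sorted(agg.items())
        if n_reads and c / n_reads >= min_frequency
    ]
    table = IndelTable(
        target=target or (None, None),
        rows=pd.DataFrame(
            rows, columns=["position", "type", "allele", "count", "frequency"]
        ),
        n_reads=n_reads,
        n_edited=n_edited,
        metadata={"cut_site_convention": CUT_SITE_CONVENTION,
                  "min_frequency": min_frequency},
    )
    return table


def classify_sgrna(edited_fraction: float, threshold: float = 0.20) -> str:
    """'strong' when the edited fraction strictly exceeds the threshold."""
    if not (0.0 <= edited_fraction <= 1.0):
        raise ValueError("edited_fraction must lie in [0, 1]")
    return "strong" if edited_fraction > threshold else "weak"


def correlate_editing_skipping(
    pairs: Iterable[tuple[Optional[float], Optional[float]]],
) -> tuple[float, int]:
    """Spearman rank correlation between editing and skipping fractions.

    Pairs with a missing member (None/NaN) — e.g. guides whose skip bands
    could not be quantified — are dropped before computing; returns
    (coefficient, n used).  Requires at least three complete pairs.
    """
    complete = [
        (e, s)
        for e, s in pairs
        if e is not None and s is not None
        and not (math.isnan(e) or math.isnan(s))
    ]
    if len(complete) < 3:
        raise InsufficientDataError("insufficient data")
    e, s = zip(*complete)
    rho = stats.spearmanr(e, s).statistic
    return float(rho), len(complete)


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_reads(
    reads: Iterable[str], ref_sequence: str, out_sam=None
) -> list[pysam.AlignedSegment]:
    """Globally align raw reads to an amplicon reference.

    Convenience path for FASTQ input; the cigar is reconstructed from the
    alignment blocks.  Scoring is pinned (match +2, mismatch -3, gap open
    -5, gap extend -1) so results are reproducible.
    """
    aligner = _pairwise_aligner()
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": "amplicon", "LN": len(ref_sequence)}],
        }
    )
    records = []
    for k, read in enumerate(reads):
        aln = aligner.align(ref_sequence, read)[0]
        tblocks, qblocks = aln.aligned
        cigar = []
        prev_t = tblocks[0][0] if len(tblocks) else 0
        prev_q = qblocks[0][0] if len(qblocks) else 0
        if prev_q > 0:
            cigar.append((4, int(prev_q)))  # leading soft clip
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            if ts > prev_t:
                cigar.append((2, int(ts - prev_t)))
            if qs > prev_q:
                cigar.append((1, int(qs - prev_q)))
            cigar.append((0, int(te - ts)))
            prev_t, prev_q = te, qe
        if len(read) > prev_q:
            cigar.append((4, int(len(read) - prev_q)))
        rec = pysam.AlignedSegment(header)
        rec.query_name = f"aln{k:07d}"
        rec.query_sequence = read
        rec.flag = 0
        rec.reference_id = 0
        rec.reference_start = int(tblocks[0][0]) if len(tblocks) else 0
        rec.mapping_quality = 60
        rec.cigartuples = cigar
        records.append(rec)
    if out_sam is not None:
        with pysam.AlignmentFile(str(out_sam), "w", header=header) as fh:
            for rec in records:
                fh.write(rec)
    return records
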