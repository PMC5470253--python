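"""Junction-read counting and the junction PSI statistic.

A junction-spanning read supports junction (i, j) when its gapped
alignment blocks end exactly at exon i's last base and resume exactly at
exon j's first base, with at least ``min_overhang`` aligned nucleotides on
both sides.  PSI for a cassette exon flanked by (up, mid, down) is

    (e(up,mid) + e(mid,down)) / (e(up,mid) + e(mid,down) + e(up,down))

i.e. inclusion is supported by two junctions and exclusion by one; the
statistic is implemented exactly in this form rather than any
length-normalized variant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import pysam

from .gene_models import GeneModel

__all__ = [
    "JunctionCounts",
    "UndefinedReductionError",
    "count_junction_reads",
    "compute_psi",
    "inclusion_counts",
    "donor_usage_fractions",
    "expression_change",
    "write_junction_tsv",
]


class UndefinedReductionError(ZeroDivisionError):
    """Parental mean is zero; percent reduction is undefined."""


@dataclass
class JunctionCounts:
    """Per-sample junction-spanning read counts for one gene.

    ``counts`` maps (donor exon label, acceptor exon label) to read
    counts; junctions whose boundaries match no annotated exon edge are
    kept separately in ``novel`` keyed by their genomic (donor end,
    acceptor start) coordinates rather than dropped.
    """

    sample_id: str
    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    novel: dict[tuple[int, int], int] = field(default_factory=dict)
    n_total_gene_reads: int = 0

    def get(self, donor: int, acceptor: int) -> int:
        return self.counts.get((donor, acceptor), 0)


def _ref_segments(rec: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference-consuming runs split at N (intron skip) operations.

    Returns 1-based inclusive segments; M/=/X/D extend the current
    segment, N closes it.
    """
    segs = []
    pos = rec.reference_start  # 0-based
    cur_start = pos
    cur_len = 0
    for op, ln in rec.cigartuples or []:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            cur_len += ln
        elif op == 3:  # N
            if cur_len:
                segs.append((cur_start + 1, cur_start + cur_len))
            cur_start = cur_start + cur_len + ln
            cur_len = 0
        # I, S, H, P consume no reference
    if cur_len:
        segs.append((cur_start + 1, cur_start + cur_len))
    return segs


def count_junction_reads(
    alignments: Union[str, Path, Iterable[pysam.AlignedSegment]],
    gene: GeneModel,
    min_overhang: int = 6,
    dedup: bool = False,
    sample_id: str = "sample",
) -> JunctionCounts:
    """Count junction-spanning reads over a gene model.

    ``alignments`` may be a SAM path or an iterable of pysam records.
    With ``dedup`` set, reads sharing (chromosome, alignment start, cigar)
    are counted once, approximating the removal of redundant read pairs
    at single-end scope.  A read spanning several junctions increments
    each.  Unmapped-only input yields empty counts with a warning.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    close_me = None
    if isinstance(alignments, (str, Path)):
        close_me = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        records: Iterable[pysam.AlignedSegment] = close_me
    else:
        records = alignments

    donor_by_end = {e.end: e.label for e in gene.exons}
    acceptor_by_start = {e.start: e.label for e in gene.exons}

    out = JunctionCounts(sample_id=sample_id)
    seen: set = set()
    n_mapped = 0
    try:
        for rec in records:
            if rec.is_unmapped:
                continue
            if rec.reference_name != gene.chrom:
                continue
            n_mapped += 1
            if dedup:
                key = (rec.reference_name, rec.reference_start, rec.cigarstring)
                if key in seen:
                    continue
                seen.add(key)
            segs = _ref_segments(rec)
            if segs and segs[0][0] <= gene.end and segs[-1][1] >= gene.start:
                out.n_total_gene_reads += 1
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if min(e1 - s1 + 1, e2 - s2 + 1) < min_overhang:
                    continue
                donor = donor_by_end.get(e1)
                acceptor = acceptor_by_start.get(s2)
                if donor is not None and acceptor is not None and donor < acceptor:
                    out.counts[(donor, acceptor)] = (
                        out.counts.get((donor, acceptor), 0) + 1
                    )
                else:
                    out.novel[(e1, s2)] = out.novel.get((e1, s2), 0) + 1
    finally:
        if close_me is not None:
            close_me.close()
    if n_mapped == 0:
        warnings.warn("no mapped reads; junction counts are empty")
    return out


def inclusion_counts(
    counts: JunctionCounts, cassette: tuple[int, int, int]
) -> tuple[int, int]:
    """(x_inclusion, m_total) for a cassette exon.

    x is the sum of the two inclusion junctions, m adds the exclusion
    junction; absent junctions read as zero.
    """
    up, mid, down = cassette
    x = counts.get(up, mid) + counts.get(mid, down)
    m = x + counts.get(up, down)
    return x, m


def compute_psi(counts: JunctionCounts, cassette: tuple[int, int, int]) -> float:
    """Junction-read PSI for a cassette exon; NaN if no informative reads."""
    x, m = inclusion_counts(counts, cassette)
    if m == 0:
        warnings.warn("no informative reads; PSI undefined")
        return math.nan
    return x / m


def donor_usage_fractions(counts: JunctionCounts, donor: int) -> dict[int, float]:
    """Fraction of junction reads leaving one donor exon per acceptor.

    Returns an empty mapping (no informative reads) when the donor has no
    outgoing junction reads.
    """
    outgoing = {
        a: c for (d, a), c in counts.counts.items() if d == donor and c > 0
    }
    total = sum(outgoing.values())
    if total == 0:
        warnings.warn("no informative reads for donor usage")
        return {}
    return {a: c / total for a, c in sorted(outgoing.items())}


def expression_change(
    clone_counts: Iterable[float], parent_counts: Iterable[float]
) -> float:
    """Percent reduction of clone mean expression relative to parent.

    100 * (1 - mean(clone) / mean(parent)); negative values indicate an
    increase.  Raises :class:`UndefinedReductionError` when the parental
    mean is zero.
    """
    clone = np.asarray(list(clone_counts), dtype=float)
    parent = np.asarray(list(parent_counts), dtype=float)
    if clone.size < 1 or parent.size < 1:
        raise ValueError("need at least one replicate per group")
    pm = parent.mean()
    if pm == 0:
        raise UndefinedReductionError("undefined reduction")
    return 100.0 * (1.0 - clone.mean() / pm)


def write_junction_tsv(counts: JunctionCounts, path, meta: Optional[dict] = None):
    """Write junction counts as TSV (sample, donor, acceptor, count)."""
    rows = [
        {"sample": counts.sample_id, "donor": d, "acceptor": a, "count": c}
        for (d, a), c in sorted(counts.counts.items())
    ]
    rows += [
        {"sample": counts.sample_id, "donor": f"novel:{d}", "acceptor": f"novel:{a}",
         "count": c}
        for (d, a), c in sorted(counts.novel.items())
    ]
    df = pd.DataFrame(rows, columns=["sample", "donor", "acceptor", "count"])
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
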