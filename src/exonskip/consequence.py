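"""Transcript- and protein-level consequences of skipping and deletion.

Three predictions, all driven by exon-label arithmetic on the gene model
rather than genomic arithmetic, so they apply unchanged to cDNA of any
isoform including deletion-derived transcripts:

* reading-frame phase of a cassette skip (in frame iff the skipped length
  is divisible by 3), with an optional scan for the first downstream ATG
  that restores the annotated frame after a frameshifting skip;
* expected RT-PCR product sizes for a primer pair across any isoform;
* interpretation of a kb-scale genomic deletion allele — which exons it
  removes, whether its breakpoints are intronic or exonic, and the
  predicted transcript (nearest-surviving-exon splice, or a fusion when a
  breakpoint interrupts an exon).

The nearest-surviving-exon rule is a deliberate simplification: splice-
site strength is not modelled, and promiscuous multi-exon skipping is
reported by the junction counter, never explained here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .gene_models import Exon, GeneModel, PrimerPair

__all__ = [
    "FrameReport",
    "DeletionAllele",
    "NotCassetteSkipError",
    "UnsupportedPrimerError",
    "DeletionOutsideGeneError",
    "frame_report",
    "predict_amplicon_size",
    "interpret_deletion",
]


class NotCassetteSkipError(ValueError):
    """Skipped exons include a terminal exon."""


class UnsupportedPrimerError(ValueError):
    """Primer does not lie fully inside one exon."""


class DeletionOutsideGeneError(ValueError):
    """Deletion interval does not overlap the gene locus."""


@dataclass(frozen=True)
class FrameReport:
    skipped_exons: tuple[int, ...]
    skipped_length: int
    in_frame: bool
    downstream_start: Optional[tuple[int, int]] = None  # (exon label, 1-based offset)


@dataclass(frozen=True)
class DeletionAllele:
    gene_id: str
    start: int
    end: int
    length: int
    removed_exons: tuple[int, ...]
    context5: str  # 'intronic' | 'exonic' | 'flanking'
    context3: str
    fusion: bool
    upstream_exon: Optional[int]
    downstream_exon: Optional[int]
    description: str


def frame_report(
    gene: GeneModel,
    skipped: list[int],
    genome: Optional[str] = None,
) -> FrameReport:
    """Reading-frame consequence of skipping internal exons.

    With a chromosome sequence supplied and the skip frameshifting, the
    downstream exons are scanned for the first ATG in the annotated
    reading frame (anchored at the first base of ``coding_start_exon``);
    translation from such a codon would yield an N-terminally truncated
    protein in the original frame.
    """
    skipped = sorted(set(skipped))
    if not skipped:
        raise ValueError("no exons to skip")
    terminal = {gene.labels[0], gene.labels[-1]}
    for lab in skipped:
        if not gene.has_exon(lab):
            raise KeyError(f"no exon labelled {lab}")
        if lab in terminal:
            raise NotCassetteSkipError("not a cassette skip")
    skipped_length = sum(gene.exon(l).length for l in skipped)
    in_frame = skipped_length % 3 == 0

    downstream_start = None
    if genome is not None and not in_frame and gene.coding_start_exon is not None:
        # annotated frame: position in full mRNA relative to the CDS start
        mrna = []
        offsets = {}
        pos = 0
        for ex in gene.exons:
            offsets[ex.label] = pos
            mrna.append(genome[ex.start - 1 : ex.end])
            pos += ex.length
        full = "".join(mrna)
        cds_start = offsets[gene.coding_start_exon]
        first_downstream = min(
            (l for l in gene.labels if l > max(skipped)), default=None
        )
        if first_downstream is not None:
            scan_from = offsets[first_downstream]
            for i in range(scan_from, len(full) - 2):
                if full[i : i + 3] == "ATG" and (i - cds_start) % 3 == 0:
                    for ex in gene.exons:
                        if offsets[ex.label] <= i < offsets[ex.label] + ex.length:
                            downstream_start = (ex.label, i - offsets[ex.label] + 1)
                            break
                    break
    return FrameReport(
        skipped_exons=tuple(skipped),
        skipped_length=skipped_length,
        in_frame=in_frame,
        downstream_start=downstream_start,
    )


def _primer_exon(gene: GeneModel, interval: tuple[str, int, int]) -> Exon:
    chrom, start, end = interval
    if chrom != gene.chrom:
        raise UnsupportedPrimerError("primer on the wrong chromosome")
    for ex in gene.exons:
        if ex.start <= start and end <= ex.end:
            return ex
        if start <= ex.end and end >= ex.start:
            raise UnsupportedPrimerError("unsupported primer placement")
    raise UnsupportedPrimerError("unsupported primer placement")


def predict_amplicon_size(
    gene: GeneModel, isoform: list[int], primers: PrimerPair
) -> Optional[int]:
    """Expected RT-PCR product length on one isoform, or None (no product).

    The product runs from the forward primer's 5' end to the reverse
    primer's 3' end along the spliced isoform: the remainder of the
    forward exon, all fully included intervening exons present in the
    isoform, and the reverse exon up to the primer end.  Returns None
    when either primer's exon is missing from the isoform.
    """
    fwd_exon = _primer_exon(gene, primers.forward)
    rev_exon = _primer_exon(gene, primers.reverse)
    if fwd_exon.label >= rev_exon.label:
        raise UnsupportedPrimerError("reverse primer must lie downstream")
    iso = list(isoform)
    if fwd_exon.label not in iso or rev_exon.label not in iso:
        return None
    _, f_start, _ = primers.forward
    _, _, r_end = primers.reverse
    size = fwd_exon.end - f_start + 1
    for lab in iso:
        if fwd_exon.label < lab < rev_exon.label:
            size += gene.exon(lab).length
    size += r_end - rev_exon.start + 1
    return size


def interpret_deletion(gene: GeneModel, start: int, end: int) -> DeletionAllele:
    """Predicted transcript consequence of a genomic deletion allele.

    Both breakpoints intronic: the nearest surviving upstream exon is
    predicted to splice to the nearest surviving downstream exon.  An
    exonic breakpoint yields a fusion transcript retaining the partial
    upstream segment joined to the surviving downstream segment.
    """
    if end < start:
        raise ValueError("end < start")
    if end < gene.start or start > gene.end:
        raise DeletionOutsideGeneError("deletion outside gene")
    length = end - start + 1
    removed = tuple(
        e.label for e in gene.exons if start <= e.start and e.end <= end
    )
    ctx5 = gene.classify_position(start)
    ctx3 = gene.classify_position(end)
    upstream = max(
        (e.label for e in gene.exons if e.end < start), default=None
    )
    downstream = min(
        (e.label for e in gene.exons if e.start > end), default=None
    )
    fusion = "exonic" in (ctx5, ctx3)

    if not fusion:
        if not removed:
            desc = "transcript unchanged (deletion confined to one intron)"
        elif upstream is not None and downstream is not None:
            desc = (
                f"exons {', '.join(map(str, removed))} removed; predicted "
                f"exon {upstream}-{downstream} junction"
            )
        else:
            desc = f"exons {', '.join(map(str, removed))} removed; terminal loss"
    else:
        parts = []
        if ctx5 == "intronic":
            # the 5' stub of the interrupted intron stays attached
            up_intron = upstream
            parts.append(f"5' end of intron {up_intron} retained")
        elif ctx5 == "exonic":
            ex5 = next(e.label for e in gene.exons if e.start <= start <= e.end)
            parts.append(f"exon {ex5} truncated at {start}")
        if ctx3 == "exonic":
            ex3 = next(e.label for e in gene.exons if e.start <= end <= e.end)
            parts.append(f"fused to the remainder of exon {ex3}")
        elif ctx3 == "intronic":
            parts.append(f"fused into the intron upstream of exon {downstream}")
        desc = "fusion transcript: " + ", ".join(parts)
    return DeletionAllele(
        gene_id=gene.gene_id,
        start=start,
        end=end,
        length=length,
        removed_exons=removed,
        context5=ctx5,
        context3=ctx3,
        fusion=fusion,
        upstream_exon=upstream,
        downstream_exon=downstream,
        description=desc,
    )
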