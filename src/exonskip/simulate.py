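"""Synthetic sequencing data with truth tables.

Everything downstream of alignment is simulated here: spliced junction
reads drawn from an isoform mixture at a known inclusion level, amplicon
deep-sequencing reads carrying a known indel spectrum, genomic alleles
with kb-scale deletions, and overdispersed gene-level count tables.  Every
generator is a pure function of its inputs and the seed, and every output
is accompanied by a truth table so recovery can be tested.

Reads are single-end with uniform placement along the mature mRNA; there
is no fragment-length or paired-end model because junction counting is the
only consumer.  Sequencing error is substitution-only, so indels in
amplicon reads come exclusively from the specified spectrum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .gene_models import GeneModel, spliced_blocks
from . import consequence as _consequence

__all__ = [
    "SimConfig",
    "IsoformMixture",
    "IndelSpectrum",
    "IndelAllele",
    "JunctionTruth",
    "ReadTooLongError",
    "InsufficientFlankError",
    "random_genome",
    "simulate_junction_reads",
    "junction_span_starts",
    "expected_junction_counts",
    "isoform_weights_for_psi",
    "simulate_amplicon_reads",
    "apply_deletion",
    "simulate_gene_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ReadTooLongError(ValueError):
    """A read length exceeds an isoform's mRNA length."""


class InsufficientFlankError(ValueError):
    """Cut site too close to an amplicon end."""


@dataclass(frozen=True)
class SimConfig:
    """Common simulation knobs.

    depth: number of reads. read_length in nt. error_rate: per-base
    substitution probability (0-0.1).
    """

    seed: int
    depth: int = 1000
    read_length: int = 75
    error_rate: float = 0.001

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must be within [0, 0.1]")
        if self.read_length < 2:
            raise ValueError("read_length too short")


@dataclass(frozen=True)
class IsoformMixture:
    """A weighted set of isoforms of one gene, each an exon-label path."""

    gene: GeneModel
    isoforms: tuple[tuple[tuple[int, ...], float], ...]

    def __post_init__(self):
        isoforms = tuple(
            (tuple(labels), float(w)) for labels, w in self.isoforms
        )
        object.__setattr__(self, "isoforms", isoforms)
        total = 0.0
        for labels, w in isoforms:
            if not (0.0 <= w <= 1.0):
                raise ValueError("isoform weights must lie in [0, 1]")
            total += w
            if list(labels) != sorted(set(labels)):
                raise ValueError("isoform labels must be strictly increasing")
            for lab in labels:
                self.gene.exon(lab)  # raises if absent
        if abs(total - 1.0) > 1e-9:
            raise ValueError("isoform weights must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.isoforms])


@dataclass(frozen=True)
class IndelAllele:
    kind: str  # 'ref', 'ins', 'del'
    value: object = None  # inserted sequence (ins) / deleted seq or length (del)
    fraction: float = 0.0


@dataclass(frozen=True)
class IndelSpectrum:
    """Allele fractions at one Cas9 cut site.

    The cut position is the 1-based reference base immediately 5' of the
    blunt cleavage (3 nt 5' of the PAM).  Insertions go in after that
    base; a deletion of length d removes the d bases ending at the cut.
    """

    target: tuple[str, int]
    alleles: tuple[IndelAllele, ...]

    def __post_init__(self):
        object.__setattr__(self, "alleles", tuple(self.alleles))
        total = 0.0
        has_ref = False
        for al in self.alleles:
            if al.kind not in ("ref", "ins", "del"):
                raise ValueError(f"unknown allele kind {al.kind!r}")
            if not (0.0 <= al.fraction <= 1.0):
                raise ValueError("allele fractions must lie in [0, 1]")
            total += al.fraction
            has_ref = has_ref or al.kind == "ref"
        if abs(total - 1.0) > 1e-9:
            raise ValueError("allele fractions must sum to 1")
        if not has_ref:
            raise ValueError("a ref allele must be present")

    @property
    def cut(self) -> int:
        return self.target[1]


def random_genome(
    length: int, seed: int, plant: Optional[dict[int, str]] = None
) -> str:
    """Random A/C/G/T sequence with optional planted motifs.

    ``plant`` maps 1-based start positions to sequences written over the
    random background (used e.g. to plant an in-frame ATG downstream of a
    frameshifting skip).
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    out = seq.tobytes().decode()
    if plant:
        buf = list(out)
        for pos, motif in plant.items():
            if pos < 1 or pos + len(motif) - 1 > length:
                raise ValueError("planted motif out of range")
            buf[pos - 1 : pos - 1 + len(motif)] = motif
        out = "".join(buf)
    return out


# ---------------------------------------------------------------------------
# Junction reads
# ---------------------------------------------------------------------------

@dataclass
class JunctionTruth:
    """Ground truth for one junction-read simulation.

    per_read: one row per read (qname, isoform index, mRNA start).
    expected: analytic expected read count per junction (floats).
    realized: exact junction-spanning read counts implied by the sampled
    placements, under the same two-sided overhang rule the counter uses.
    """

    per_read: pd.DataFrame
    expected: dict[tuple[int, int], float]
    realized: dict[tuple[int, int], int]
    target_psi: Optional[float] = None
    min_overhang: int = 6


def junction_span_starts(
    boundary: int, mrna_len: int, read_length: int, min_overhang: int
) -> int:
    """Number of read start positions spanning an mRNA junction.

    ``boundary`` is the 0-based transcript position of the first base of
    the downstream exon; a read [s, s+L) spans with overhang ``o`` iff
    s <= boundary - o and s + L >= boundary + o.
    """
    s_min = max(0, boundary + min_overhang - read_length)
    s_max = min(boundary - min_overhang, mrna_len - read_length)
    return max(0, s_max - s_min + 1)


def _isoform_junction_boundaries(gene, labels):
    """(junction, 0-based boundary position in this isoform's mRNA)."""
    out = []
    offset = 0
    for a, b in zip(labels, labels[1:]):
        offset += gene.exon(a).length
        out.append(((a, b), offset))
    return out


def expected_junction_counts(
    mix: IsoformMixture, cfg: SimConfig, min_overhang: int = 6
) -> dict[tuple[int, int], float]:
    """Analytic expected junction-read counts for a mixture."""
    out: dict[tuple[int, int], float] = {}
    for (labels, w) in mix.isoforms:
        L = mix.gene.mrna_length(list(labels))
        n_starts = L - cfg.read_length + 1
        if n_starts <= 0:
            raise ReadTooLongError("read too long")
        for junc, boundary in _isoform_junction_boundaries(mix.gene, labels):
            k = junction_span_starts(boundary, L, cfg.read_length, min_overhang)
            out[junc] = out.get(junc, 0.0) + cfg.depth * w * k / n_starts
    return out


def isoform_weights_for_psi(
    gene: GeneModel,
    cassette: tuple[int, int, int],
    psi: float,
    cfg: SimConfig,
    min_overhang: int = 6,
) -> IsoformMixture:
    """Two-isoform mixture whose junction-read PSI expectation equals ``psi``.

    PSI is computed from junction counts as
    (e(up,mid) + e(mid,down)) / (e(up,mid) + e(mid,down) + e(up,down)),
    which counts each inclusion read-pair of junctions twice relative to
    the single exclusion junction; the inclusion-isoform weight solving
    for a target PSI therefore differs from PSI itself.  This helper does
    the inversion so simulations can be phrased directly in PSI units.
    """
    if not (0.0 <= psi <= 1.0):
        raise ValueError("psi must lie in [0, 1]")
    up, mid, down = cassette
    inc = tuple(l for l in gene.labels if True)  # full isoform
    exc = tuple(l for l in gene.labels if l != mid)
    L_inc = gene.mrna_length(list(inc))
    L_exc = gene.mrna_length(list(exc))
    n_inc = L_inc - cfg.read_length + 1
    n_exc = L_exc - cfg.read_length + 1
    if n_inc <= 0 or n_exc <= 0:
        raise ReadTooLongError("read too long")
    b_incl = dict(_isoform_junction_boundaries(gene, inc))
    b_excl = dict(_isoform_junction_boundaries(gene, exc))
    k_um = junction_span_starts(b_incl[(up, mid)], L_inc, cfg.read_length, min_overhang)
    k_md = junction_span_starts(b_incl[(mid, down)], L_inc, cfg.read_length, min_overhang)
    k_ud = junction_span_starts(b_excl[(up, down)], L_exc, cfg.read_length, min_overhang)
    a = (k_um + k_md) / n_inc  # inclusion junction reads per unit weight
    b = k_ud / n_exc           # exclusion junction reads per unit weight
    if psi in (0.0, 1.0):
        w = psi
    else:
        w = psi * b / (a * (1 - psi) + psi * b)
    return IsoformMixture(gene=gene, isoforms=((inc, w), (exc, 1.0 - w)))


def _sam_header(gene: GeneModel, chrom_len: int) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": gene.chrom, "LN": chrom_len}],
        }
    )


def simulate_junction_reads(
    mix: IsoformMixture,
    cfg: SimConfig,
    out_sam,
    min_overhang: int = 6,
    genome: Optional[str] = None,
    target_psi: Optional[float] = None,
    duplicate_fraction: float = 0.0,
) -> JunctionTruth:
    """Draw spliced single-end reads from an isoform mixture.

    Each read picks an isoform by weight, then a start uniformly over the
    valid transcript positions; the emitted SAM record's gapped blocks
    match the genomic exon structure.  ``duplicate_fraction`` re-emits
    that fraction of reads verbatim (new names) to exercise deduplication.
    Returns the :class:`JunctionTruth` table.
    """
    gene = mix.gene
    for labels, _ in mix.isoforms:
        if len(labels) < 2:
            raise ValueError("every isoform needs at least 2 exons")
        if gene.mrna_length(list(labels)) < cfg.read_length:
            raise ReadTooLongError("read too long")
    rng = np.random.default_rng(cfg.seed)
    chrom_len = gene.end + 200
    if genome is None:
        genome = random_genome(chrom_len, seed=int(rng.integers(2**31)))
    else:
        chrom_len = len(genome)

    iso_idx = rng.choice(len(mix.isoforms), size=cfg.depth, p=mix.weights)
    rows = []
    realized: dict[tuple[int, int], int] = {}
    header = _sam_header(gene, chrom_len)
    records = []
    for k in range(cfg.depth):
        labels, _ = mix.isoforms[iso_idx[k]]
        L = gene.mrna_length(list(labels))
        start = int(rng.integers(0, L - cfg.read_length + 1))
        blocks = spliced_blocks(gene, list(labels), start, cfg.read_length)
        seq = "".join(genome[s - 1 : e] for s, e in blocks)
        # substitution errors
        if cfg.error_rate > 0:
            errs = np.flatnonzero(rng.random(cfg.read_length) < cfg.error_rate)
            if errs.size:
                buf = list(seq)
                for i in errs:
                    alts = [b for b in "ACGT" if b != buf[i]]
                    buf[i] = alts[int(rng.integers(3))]
                seq = "".join(buf)
        cigar = []
        for i, (s, e) in enumerate(blocks):
            if i:
                gap = s - blocks[i - 1][1] - 1
                cigar.append((3, gap))  # N
            cigar.append((0, e - s + 1))  # M
        rec = pysam.AlignedSegment(header)
        rec.query_name = f"read{k:07d}"
        rec.query_sequence = seq
        rec.flag = 0
        rec.reference_id = 0
        rec.reference_start = blocks[0][0] - 1
        rec.mapping_quality = 60
        rec.cigartuples = cigar
        rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        records.append(rec)
        rows.append((rec.query_name, int(iso_idx[k]), start))
        for junc, boundary in _isoform_junction_boundaries(gene, labels):
            if (
                start <= boundary - min_overhang
                and start + cfg.read_length >= boundary + min_overhang
            ):
                realized[junc] = realized.get(junc, 0) + 1

    if duplicate_fraction > 0.0:
        n_dup = int(round(duplicate_fraction * cfg.depth))
        picks = rng.choice(cfg.depth, size=n_dup, replace=True)
        for j, p in enumerate(picks):
            src = records[int(p)]
            dup = pysam.AlignedSegment(header)
            dup.query_name = f"dup{j:07d}"
            dup.query_sequence = src.query_sequence
            dup.flag = 0
            dup.reference_id = 0
            dup.reference_start = src.reference_start
            dup.mapping_quality = 60
            dup.cigartuples = src.cigartuples
            dup.query_qualities = src.query_qualities
            records.append(dup)

    with pysam.AlignmentFile(str(out_sam), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)

    expected = expected_junction_counts(mix, cfg, min_overhang)
    per_read = pd.DataFrame(rows, columns=["qname", "isoform", "mrna_start"])
    return JunctionTruth(
        per_read=per_read,
        expected=expected,
        realized=realized,
        target_psi=target_psi,
        min_overhang=min_overhang,
    )


# ---------------------------------------------------------------------------
# Amplicon reads
# ---------------------------------------------------------------------------

def _apply_allele(ref: str, cut: int, allele: IndelAllele) -> tuple[str, list]:
    """Mutated amplicon sequence and cigartuples for one allele."""
    n = len(ref)
    if allele.kind == "ref":
        return ref, [(0, n)]
    if allele.kind == "ins":
        ins = str(allele.value)
        seq = ref[:cut] + ins + ref[cut:]
        return seq, [(0, cut), (1, len(ins)), (0, n - cut)]
    # deletion: remove d bases ending at the cut
    if isinstance(allele.value, int):
        d = allele.value
    else:
        d = len(str(allele.value))
        expect = ref[cut - d : cut]
        if expect != str(allele.value):
            raise ValueError(
                f"deletion allele {allele.value!r} does not match reference "
                f"bases {expect!r} at the cut"
            )
    if d >= cut:
        raise ValueError("deletion extends past the amplicon start")
    seq = ref[: cut - d] + ref[cut:]
    return seq, [(0, cut - d), (2, d), (0, n - cut)]


def simulate_amplicon_reads(
    spectrum: IndelSpectrum,
    ref_sequence: str,
    cfg: SimConfig,
    out_sam=None,
    out_fastq=None,
) -> tuple[list[str], pd.DataFrame]:
    """Amplicon deep-sequencing reads carrying a known indel spectrum.

    Each read is a full-length copy of the amplicon with one allele drawn
    by its fraction, plus substitution errors at ``cfg.error_rate``.
    Returns (read sequences, truth table of per-allele counts).
    """
    cut = spectrum.cut
    if cut < 20 or len(ref_sequence) - cut < 20:
        raise InsufficientFlankError("insufficient flank")
    rng = np.random.default_rng(cfg.seed)
    fractions = np.array([al.fraction for al in spectrum.alleles])
    picks = rng.choice(len(spectrum.alleles), size=cfg.depth, p=fractions)
    templates = [
        _apply_allele(ref_sequence, cut, al) for al in spectrum.alleles
    ]
    reads = []
    sam_records = []
    header = None
    if out_sam is not None:
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [{"SN": spectrum.target[0], "LN": len(ref_sequence)}],
            }
        )
    for k in range(cfg.depth):
        seq, cigar = templates[picks[k]]
        if cfg.error_rate > 0:
            errs = np.flatnonzero(rng.random(len(seq)) < cfg.error_rate)
            if errs.size:
                buf = list(seq)
                for i in errs:
                    alts = [b for b in "ACGT" if b != buf[i]]
                    buf[i] = alts[int(rng.integers(3))]
                seq = "".join(buf)
        reads.append(seq)
        if header is not None:
            rec = pysam.AlignedSegment(header)
            rec.query_name = f"amp{k:07d}"
            rec.query_sequence = seq
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = 0
            rec.mapping_quality = 60
            rec.cigartuples = cigar
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            sam_records.append(rec)
    if out_sam is not None:
        with pysam.AlignmentFile(str(out_sam), "w", header=header) as fh:
            for rec in sam_records:
                fh.write(rec)
    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            for k, seq in enumerate(reads):
                fh.write(f"@amp{k:07d}\n{seq}\n+\n{'I' * len(seq)}\n")
    counts = np.bincount(picks, minlength=len(spectrum.alleles))
    truth = pd.DataFrame(
        {
            "kind": [al.kind for al in spectrum.alleles],
            "value": [al.value for al in spectrum.alleles],
            "fraction": fractions,
            "count": counts,
        }
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Genomic deletions and gene-level counts
# ---------------------------------------------------------------------------

def apply_deletion(
    gene: GeneModel, genome_sequence: str, breakpoints: tuple[int, int]
):
    """Delete the closed interval [start, end] from a genome sequence.

    Returns the mutated sequence and the interpreted
    :class:`~exonskip.consequence.DeletionAllele` truth for the gene.
    """
    start, end = breakpoints
    if not (1 <= start <= end <= len(genome_sequence)):
        raise ValueError("out of range")
    mutated = genome_sequence[: start - 1] + genome_sequence[end:]
    truth = _consequence.interpret_deletion(gene, start, end)
    return mutated, truth


def simulate_gene_counts(
    base_mean: float,
    reduction: float,
    n_replicates: int,
    seed: int,
    dispersion: float = 0.01,
    n_parent_replicates: Optional[int] = None,
) -> tuple[pd.DataFrame, dict]:
    """Overdispersed gene-level read counts for parent and edited clone.

    Counts are negative binomial with variance mu + dispersion * mu^2;
    the default dispersion 0.01 (CV ~10% at high expression) is typical of
    well-expressed genes across cell-line replicates.  Clone replicates
    have mean ``base_mean * (1 - reduction)``.
    """
    if not (0.0 <= reduction < 1.0):
        raise ValueError("reduction must lie in [0, 1)")
    if base_mean <= 0 or n_replicates < 1:
        raise ValueError("base_mean and n_replicates must be positive")
    if n_parent_replicates is None:
        n_parent_replicates = n_replicates
    rng = np.random.default_rng(seed)

    def draw(mu, n):
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p, size=n)

    parent = draw(base_mean, n_parent_replicates)
    clone = draw(base_mean * (1.0 - reduction), n_replicates)
    df = pd.DataFrame(
        {
            "group": ["parent"] * n_parent_replicates + ["clone"] * n_replicates,
            "replicate": list(range(1, n_parent_replicates + 1))
            + list(range(1, n_replicates + 1)),
            "count": np.concatenate([parent, clone]),
        }
    )
    truth = {"reduction": reduction, "base_mean": base_mean, "dispersion": dispersion}
    return df, truth
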