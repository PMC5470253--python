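"""Gene models on toy chromosomes: loading, validation, fixtures.

A :class:`GeneModel` is an ordered list of labelled exons on one chromosome.
Coordinates are 1-based inclusive throughout (the GTF convention).  Exon
labels are the biological exon numbers and need not start at 1 — the
beta-catenin fixture, for example, starts at exon 2 because the upstream
exons play no role in the assays modelled here.

Four packaged fixtures mirror the loci studied in CRISPR exon-skipping
experiments (mouse Kras exon 2, Ctnnb1 exon 3, Dmd exon 23, p65/RelA
exon 6).  Their coordinates are toy values constrained only by published
product sizes and lesion lengths, not by any real genome assembly.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import gffutils

__all__ = [
    "Exon",
    "GeneModel",
    "PrimerPair",
    "GeneNotFoundError",
    "MalformedModelError",
    "NoSuchFixtureError",
    "load_gene_model",
    "write_gtf",
    "build_fixture",
    "FIXTURE_NAMES",
    "spliced_blocks",
]


class GeneNotFoundError(KeyError):
    """Requested gene_id is absent from the annotation file."""


class MalformedModelError(ValueError):
    """Exon list violates the gene-model invariants."""


class NoSuchFixtureError(KeyError):
    """Unknown fixture name."""


@dataclass(frozen=True)
class Exon:
    label: int
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PrimerPair:
    """An RT-PCR primer pair; both primers 1-based inclusive intervals.

    The forward primer lies fully inside one exon on the mRNA sense
    strand; the reverse primer anneals within one downstream exon.
    """

    forward: tuple[str, int, int]
    reverse: tuple[str, int, int]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    coding_start_exon: Optional[int] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise MalformedModelError(f"malformed model: bad strand {self.strand!r}")
        if not self.exons:
            raise MalformedModelError("malformed model: no exons")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        prev = None
        for ex in exons:
            if ex.end < ex.start:
                raise MalformedModelError(
                    f"malformed model: exon {ex.label} end < start"
                )
            if prev is not None:
                if ex.start <= prev.end:
                    raise MalformedModelError(
                        f"malformed model: exons {prev.label} and {ex.label} "
                        "overlap or are unsorted"
                    )
                if ex.label <= prev.label:
                    raise MalformedModelError(
                        "malformed model: exon labels must be strictly increasing"
                    )
            prev = ex
        if self.coding_start_exon is not None:
            self.exon(self.coding_start_exon)

    # -- accessors ---------------------------------------------------------

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(e.label for e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def exon(self, label: int) -> Exon:
        for e in self.exons:
            if e.label == label:
                return e
        raise KeyError(f"no exon labelled {label} in {self.gene_id}")

    def has_exon(self, label: int) -> bool:
        return any(e.label == label for e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Maximal gaps between consecutive exons, 1-based inclusive."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append((a.end + 1, b.start - 1))
        return out

    def intron_after(self, label: int) -> tuple[int, int]:
        ex = self.exon(label)
        idx = self.exons.index(ex)
        if idx == len(self.exons) - 1:
            raise KeyError(f"exon {label} is the last exon")
        return (ex.end + 1, self.exons[idx + 1].start - 1)

    def mrna_length(self, labels: Optional[list[int]] = None) -> int:
        if labels is None:
            return sum(e.length for e in self.exons)
        return sum(self.exon(l).length for l in labels)

    def classify_position(self, pos: int) -> str:
        """'exonic', 'intronic' (within the locus) or 'flanking'."""
        if pos < self.start or pos > self.end:
            return "flanking"
        for e in self.exons:
            if e.start <= pos <= e.end:
                return "exonic"
        return "intronic"


def spliced_blocks(
    gene: GeneModel, labels: list[int], mrna_start: int, length: int
) -> list[tuple[int, int]]:
    """Genomic blocks (1-based inclusive) covered by an mRNA interval.

    ``mrna_start`` is 0-based on the spliced transcript built from
    ``labels``; ``length`` is the number of transcript bases.  Returns the
    per-exon genomic segments in coordinate order.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    blocks = []
    offset = 0
    remaining = length
    pos = mrna_start
    for lab in labels:
        ex = gene.exon(lab)
        if pos < offset + ex.length and remaining > 0:
            local = max(pos - offset, 0)
            take = min(ex.length - local, remaining)
            blocks.append((ex.start + local, ex.start + local + take - 1))
            remaining -= take
        offset += ex.length
    if remaining > 0:
        raise ValueError("interval extends past the end of the transcript")
    return blocks


# ---------------------------------------------------------------------------
# GTF / BED12 input and output
# ---------------------------------------------------------------------------

def _reflect_minus_strand(exons: list[Exon]) -> list[Exon]:
    # Reflect coordinates about the locus span so that transcription order
    # becomes ascending; labels travel with their exons.
    lo = min(e.start for e in exons)
    hi = max(e.end for e in exons)
    pivot = lo + hi
    out = [Exon(e.label, pivot - e.end, pivot - e.start) for e in exons]
    return sorted(out, key=lambda e: e.start)


def _finish_model(gene_id, chrom, strand, raw_exons, coding_start_exon=None):
    exons = sorted(set(raw_exons), key=lambda e: (e.start, e.end))
    for a, b in zip(exons, exons[1:]):
        if b.start <= a.end:
            raise MalformedModelError(
                f"malformed model: overlapping exons in {gene_id}"
            )
    if strand == "-":
        exons = _reflect_minus_strand(exons)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        coding_start_exon=coding_start_exon,
    )


def _load_gtf(path: Path, gene_id: str) -> GeneModel:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    raw = []
    strand = None
    chrom = None
    n = 0
    start_codon_pos = None
    for feat in db.all_features():
        if feat.attributes.get("gene_id", [None])[0] != gene_id:
            continue
        if feat.featuretype == "start_codon":
            start_codon_pos = feat.start
            continue
        if feat.featuretype != "exon":
            continue
        n += 1
        chrom = feat.seqid
        strand = feat.strand
        number = feat.attributes.get("exon_number", [None])[0]
        raw.append((feat.start, feat.end, int(number) if number else None))
    if n == 0:
        raise GeneNotFoundError(f"gene not found: {gene_id}")
    raw = sorted(set(raw))
    if any(num is None for _, _, num in raw):
        order = raw if strand == "+" else raw[::-1]
        numbered = {(s, e): i + 1 for i, (s, e, _) in enumerate(order)}
        exons = [Exon(numbered[(s, e)], s, e) for s, e, _ in raw]
    else:
        exons = [Exon(num, s, e) for s, e, num in raw]
    coding_start_exon = None
    if start_codon_pos is not None:
        for ex in exons:
            if ex.start <= start_codon_pos <= ex.end:
                coding_start_exon = ex.label
                break
    return _finish_model(gene_id, chrom, strand, exons, coding_start_exon)


def _load_bed12(path: Path, gene_id: str) -> GeneModel:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise MalformedModelError("malformed model: not a BED12 line")
            if f[3] != gene_id:
                continue
            chrom, chrom_start, strand = f[0], int(f[1]), f[5]
            count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != count or len(starts) != count:
                raise MalformedModelError("malformed model: block fields disagree")
            exons = []
            for i, (bs, sz) in enumerate(zip(starts, sizes)):
                g0 = chrom_start + bs  # 0-based
                exons.append(Exon(i + 1, g0 + 1, g0 + sz))
            if strand == "-":
                exons = [replace(e, label=count - e.label + 1) for e in exons]
            return _finish_model(gene_id, chrom, strand, exons)
    raise GeneNotFoundError(f"gene not found: {gene_id}")


def load_gene_model(path, gene_id: str, fmt: Optional[str] = None) -> GeneModel:
    """Load one gene from a GTF or BED12 file.

    The dialect is taken from ``fmt`` ('gtf' or 'bed') or guessed from the
    file suffix.  GTF exon records sharing coordinates (e.g. from several
    transcripts of the same gene) are merged into a single exon list.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() in (".bed", ".bed12") else "gtf"
    if fmt == "bed":
        return _load_bed12(path, gene_id)
    return _load_gtf(path, gene_id)


def write_gtf(model: GeneModel, path) -> None:
    """Write the model as GTF exon records (one toy transcript per gene)."""
    tx = f"{model.gene_id}.t1"
    with open(path, "w") as fh:
        if model.coding_start_exon is not None:
            cs = model.exon(model.coding_start_exon)
            attrs = f'gene_id "{model.gene_id}"; transcript_id "{tx}";'
            fh.write(
                "\t".join(
                    [
                        model.chrom,
                        "exonskip",
                        "start_codon",
                        str(cs.start),
                        str(cs.start + 2),
                        ".",
                        model.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )
        for ex in model.exons:
            attrs = (
                f'gene_id "{model.gene_id}"; transcript_id "{tx}"; '
                f'exon_number "{ex.label}";'
            )
            fh.write(
                "\t".join(
                    [
                        model.chrom,
                        "exonskip",
                        "exon",
                        str(ex.start),
                        str(ex.end),
                        ".",
                        model.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("kras", "ctnnb1", "dmd", "p65")


def _kras():
    model = GeneModel(
        gene_id="KrasToy",
        chrom="chrK",
        strand="+",
        exons=(Exon(1, 1, 200), Exon(2, 501, 622), Exon(3, 1001, 1400)),
        coding_start_exon=1,
    )
    primers = PrimerPair(forward=("chrK", 138, 159), reverse=("chrK", 1124, 1146))
    meta = {
        "cassette": (1, 2, 3),
        "target_exon": 2,
        # frameshifting small deletions observed in the two edited clones
        "lesions": {"KP1": ["-CG", "-C"], "KP2": ["-GG"]},
    }
    return model, primers, meta


def _dmd():
    model = GeneModel(
        gene_id="DmdToy",
        chrom="chrD",
        strand="+",
        exons=(Exon(22, 1, 300), Exon(23, 1001, 1213), Exon(24, 2001, 2300)),
        coding_start_exon=22,
    )
    primers = PrimerPair(forward=("chrD", 209, 230), reverse=("chrD", 2027, 2048))
    meta = {"cassette": (22, 23, 24), "target_exon": 23}
    return model, primers, meta


def _ctnnb1():
    model = GeneModel(
        gene_id="Ctnnb1Toy",
        chrom="chrC",
        strand="+",
        exons=(
            Exon(2, 1, 150),
            Exon(3, 401, 628),
            Exon(4, 901, 1084),
            Exon(5, 1301, 1399),
            Exon(6, 1601, 1750),
            Exon(7, 2001, 2200),
        ),
        coding_start_exon=2,
    )
    # sg1 cleaves after nucleotide 97 of exon 3 (genomic 497); the most
    # frequent repair product is a +T insertion at the cut.
    meta = {
        "cassette": (2, 3, 4),
        "target_exon": 3,
        "cut_site": {"exon": 3, "offset": 97, "genomic": 497},
        "deletion_allele": (160, 991),  # 832 bp, intron 2 into exon 4
    }
    return model, None, meta


def _p65():
    model = GeneModel(
        gene_id="P65Toy",
        chrom="chrP",
        strand="+",
        exons=(
            Exon(4, 1, 150),
            Exon(5, 1001, 1100),
            Exon(6, 1501, 1600),
            Exon(7, 2101, 2200),
            Exon(8, 3001, 3150),
        ),
        coding_start_exon=4,
    )
    meta = {
        "target_exon": 6,
        "deletion_allele": (400, 2667),  # 2268 bp, removes exons 5-7
    }
    return model, None, meta


_FIXTURES = {"kras": _kras, "dmd": _dmd, "ctnnb1": _ctnnb1, "p65": _p65}


def build_fixture(name: str):
    """Return ``(GeneModel, PrimerPair or None, metadata dict)`` for a locus.

    Recognized names: kras, ctnnb1, dmd, p65.
    """
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise NoSuchFixtureError(f"no such fixture: {name}") from None
    return factory()


def fixture_gtf_path(name: str) -> Path:
    """Path of the packaged GTF file for a fixture."""
    if name not in _FIXTURES:
        raise NoSuchFixtureError(f"no such fixture: {name}")
    return Path(__file__).parent / "data" / f"{name}.gtf"
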