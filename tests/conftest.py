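import pysam
import pytest

from exonskip.gene_models import GeneModel, build_fixture


@pytest.fixture(scope="session")
def kras():
    return build_fixture("kras")


@pytest.fixture(scope="session")
def ctnnb1():
    return build_fixture("ctnnb1")


@pytest.fixture(scope="session")
def dmd():
    return build_fixture("dmd")


@pytest.fixture(scope="session")
def p65():
    return build_fixture("p65")


def sam_header(gene: GeneModel, length: int = None) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": gene.chrom, "LN": length or gene.end + 200}],
        }
    )


def make_read(header, name, start1, cigartuples, chrom_idx=0, seq=None):
    """Build an aligned pysam record; start1 is 1-based."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = 0
    rec.reference_id = chrom_idx
    rec.reference_start = start1 - 1
    rec.mapping_quality = 60
    rec.cigartuples = cigartuples
    qlen = sum(ln for op, ln in cigartuples if op in (0, 1, 4, 7, 8))
    rec.query_sequence = seq or ("A" * qlen)
    return rec


def brute_force_expected_junctions(mix, cfg, min_overhang):
    """Independent oracle: enumerate every (isoform, start) placement and
    count junction overlaps exactly, weighting by isoform probability."""
    out = {}
    for labels, w in mix.isoforms:
        gene = mix.gene
        lens = [gene.exon(l).length for l in labels]
        L = sum(lens)
        n_starts = L - cfg.read_length + 1
        boundaries = []
        off = 0
        for (a, b), ln in zip(zip(labels, labels[1:]), lens):
            off += ln
            boundaries.append(((a, b), off))
        for start in range(n_starts):
            for junc, boundary in boundaries:
                left = boundary - start
                right = start + cfg.read_length - boundary
                if left >= min_overhang and right >= min_overhang:
                    out[junc] = out.get(junc, 0.0) + w * cfg.depth / n_starts
    return out
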