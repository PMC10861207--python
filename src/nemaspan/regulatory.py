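"""DEG filtering and SKN-1 consensus-motif scanning of promoters.

Differential-expression tables are filtered at the standard thresholds
(fold change >= 2, i.e. |log2FC| >= 1, and FDR <= 0.05, both inclusive),
and the 1.5-kb regions upstream of each gene are scanned for the
degenerate SKN-1/Nrf binding consensus motifs TTDTCATC and WWTRTCAT
(D = A/G/T, W = A/T, R = A/G) to flag putative direct targets.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SKN1_MOTIFS",
    "DegRecord",
    "IupacMotif",
    "PromoterSeq",
    "MotifHit",
    "filter_degs",
    "expand_iupac",
    "scan_motifs",
    "annotate_degs_with_sites",
    "extract_promoters",
]

# supported degenerate codes; subject-side N never matches
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "D": "AGT", "W": "AT", "R": "AG",
}


@dataclass(frozen=True)
class DegRecord:
    """One row of a differential-expression table."""

    gene_id: str
    log2fc: float
    fdr: float

    def __post_init__(self):
        if not 0 <= self.fdr <= 1:
            raise ValueError(f"gene {self.gene_id!r}: fdr {self.fdr} outside [0, 1]")

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass(frozen=True)
class IupacMotif:
    """Degenerate consensus pattern over {A,C,G,T,D,W,R} with its full
    concrete-word expansion."""

    pattern: str
    expansion: frozenset = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "pattern", self.pattern.upper())
        object.__setattr__(self, "expansion", frozenset(expand_iupac(self.pattern)))

    def __len__(self) -> int:
        return len(self.pattern)

    def reverse_complement(self) -> str:
        """Concrete regex-free RC is not defined for degenerate codes in
        general; return the RC of the pattern over the supported codes."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A",
                "D": "H", "W": "W", "R": "Y", "H": "D", "Y": "R"}
        return "".join(comp[c] for c in reversed(self.pattern))

    def regex(self) -> re.Pattern:
        return re.compile("".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
            for c in self.pattern
        ))


@dataclass(frozen=True)
class PromoterSeq:
    """Upstream regulatory sequence for one gene, uppercased; 1500 nt by
    design unless truncated by a contig edge."""

    gene_id: str
    seq: str
    source: str = "provided_fasta"
    truncated: bool = False

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"promoter {self.gene_id!r}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 0-based half-open [start, start+len) on the
    provided promoter sequence; for '-' strand hits ``matched_word`` is
    the reverse complement of the promoter slice (i.e. the word as read
    on the minus strand)."""

    gene_id: str
    pattern: str
    strand: str
    start: int
    matched_word: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_word)


def filter_degs(
    records, fc_min: float = 2.0, fdr_max: float = 0.05
) -> tuple[list[DegRecord], list[DegRecord], list[str]]:
    """Split records into (up, down, rejects) at inclusive thresholds.

    Keeps a record iff |log2fc| >= log2(fc_min) and fdr <= fdr_max.
    Records with FDR outside [0, 1] are rejected with a message rather
    than raising, so one bad row does not abort a table.
    """
    import math

    log2_min = math.log2(fc_min)
    up, down, rejects = [], [], []
    for r in records:
        if not isinstance(r, DegRecord):
            try:
                r = DegRecord(*r)
            except ValueError as e:
                rejects.append(str(e))
                continue
        if abs(r.log2fc) >= log2_min and r.fdr <= fdr_max:
            (up if r.log2fc > 0 else down).append(r)
    return up, down, rejects


def expand_iupac(pattern: str) -> set[str]:
    """Full Cartesian expansion of a degenerate pattern into concrete words."""
    pattern = pattern.upper()
    unsupported = set(pattern) - set(IUPAC_CODES)
    if unsupported:
        raise ValueError(f"unsupported IUPAC codes: {sorted(unsupported)}")
    return {"".join(w) for w in itertools.product(*(IUPAC_CODES[c] for c in pattern))}


#: the two degenerate SKN-1/Nrf binding consensus patterns
SKN1_MOTIFS = (IupacMotif("TTDTCATC"), IupacMotif("WWTRTCAT"))


def scan_motifs(
    promoter: PromoterSeq,
    motifs=SKN1_MOTIFS,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences in a promoter.

    Plus-strand hits match the motif directly; minus-strand hits are
    found by matching the reverse-complemented motif against the plus
    strand, so reported coordinates always refer to the provided
    sequence.  N in the subject never matches.  Hits are sorted by
    (start, strand, pattern).
    """
    seq = promoter.seq
    hits: list[MotifHit] = []
    for motif in motifs:
        if len(seq) < len(motif):
            continue
        pat = motif.regex()
        for m in _finditer_overlapping(pat, seq):
            hits.append(MotifHit(promoter.gene_id, motif.pattern, "+",
                                 m.start(), m.group()))
        if both_strands:
            rc_words = {str(Seq(w).reverse_complement()) for w in motif.expansion}
            rc_pat = re.compile("|".join(sorted(rc_words)))
            for m in _finditer_overlapping(rc_pat, seq):
                word = str(Seq(m.group()).reverse_complement())
                hits.append(MotifHit(promoter.gene_id, motif.pattern, "-",
                                     m.start(), word))
    hits.sort(key=lambda h: (h.start, h.strand, h.pattern))
    return hits


def _finditer_overlapping(pattern: re.Pattern, seq: str):
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return
        yield m
        pos = m.start() + 1


def annotate_degs_with_sites(
    degs: list[DegRecord],
    promoters: list[PromoterSeq],
    motifs=SKN1_MOTIFS,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Per-gene motif-site counts for a DEG list.

    Genes without a supplied promoter get ``n_sites = NaN`` and
    ``has_site = None`` (unknown, not zero).  Duplicate promoter ids are
    an error because the count would be ambiguous.
    """
    by_gene: dict[str, PromoterSeq] = {}
    for p in promoters:
        if p.gene_id in by_gene:
            raise ValueError(f"duplicate promoter for gene {p.gene_id!r}")
        by_gene[p.gene_id] = p

    rows = []
    for deg in degs:
        prom = by_gene.get(deg.gene_id)
        if prom is None:
            rows.append({"gene_id": deg.gene_id, "n_sites": float("nan"),
                         "has_site": None, "direction": deg.direction})
        else:
            n = len(scan_motifs(prom, motifs, both_strands))
            rows.append({"gene_id": deg.gene_id, "n_sites": float(n),
                         "has_site": n >= 1, "direction": deg.direction})
    return pd.DataFrame(rows, columns=["gene_id", "n_sites", "has_site", "direction"])


def extract_promoters(
    genome: dict[str, str],
    annotations: pd.DataFrame,
    flank: int = 1500,
) -> list[PromoterSeq]:
    """Strand-aware upstream flanks from a genome and gene features.

    ``annotations`` needs columns gene_id, contig, start, end, strand
    with 1-based inclusive coordinates (the standard annotation
    convention).  For '+' genes the promoter is the ``flank`` bases
    ending immediately before ``start``; for '-' genes, the ``flank``
    bases beginning immediately after ``end``, reverse-complemented so
    the returned sequence reads 5'->3' toward the gene.  Flanks clipped
    by a contig edge are returned shorter and flagged.
    """
    out = []
    for row in annotations.itertuples(index=False):
        if row.contig not in genome:
            raise ValueError(f"gene {row.gene_id!r}: contig {row.contig!r} not in genome")
        contig_seq = genome[row.contig]
        if row.strand == "+":
            hi = int(row.start) - 1          # 0-based exclusive end
            lo = max(0, hi - flank)
            seq = contig_seq[lo:hi]
        elif row.strand == "-":
            lo = int(row.end)                # 0-based inclusive start
            hi = min(len(contig_seq), lo + flank)
            seq = str(Seq(contig_seq[lo:hi]).reverse_complement())
        else:
            raise ValueError(f"gene {row.gene_id!r}: invalid strand {row.strand!r}")
        out.append(PromoterSeq(gene_id=row.gene_id, seq=seq, source="extracted",
                               truncated=len(seq) < flank))
    return out
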