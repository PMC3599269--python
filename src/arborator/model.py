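"""Domain types shared across the pipeline.

Coordinates are 0-based half-open throughout the package; GFF3 on disk is
1-based inclusive and converted at the IO boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field


VALID_BASES = frozenset("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class GenomeSequence:
    """One chromosome/scaffold: an uppercase DNA string over {A,C,G,T,N}."""

    chrom_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.chrom_id}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"{self.chrom_id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


def genome_dict(records: list[GenomeSequence]) -> dict[str, str]:
    """chrom_id -> seq mapping; chrom ids must be unique."""
    out: dict[str, str] = {}
    for r in records:
        if r.chrom_id in out:
            raise ValueError(f"duplicate chrom_id {r.chrom_id}")
        out[r.chrom_id] = r.seq
    return out


@dataclass
class GeneModel:
    """A located, stranded, possibly multi-exon coding feature."""

    gene_id: str
    chrom_id: str
    strand: str
    exons: list[tuple[int, int]]
    has_intron: bool = False
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        ex = sorted(self.exons)
        if ex != list(self.exons):
            raise ValueError(f"{self.gene_id}: exons not sorted by start")
        for (s, e) in ex:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
        for (_, e1), (s2, _) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.cds_len < 3:
            raise ValueError(f"{self.gene_id}: CDS shorter than one codon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class TRNAModel:
    trna_id: str
    chrom_id: str
    strand: str
    start: int
    end: int
    isotype: str = "X"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class HitRecord:
    """One ranked protein-to-genome hit (aligner stand-in).

    ``rank`` is 1-based within a query; rank 1 is the best-scoring hit.
    """

    query_id: str
    chrom_id: str
    start: int
    end: int
    strand: str
    score: float
    rank: int | None = None


@dataclass
class VariantCall:
    """A SNP or a small indel, 0-based.

    SNP: |ref| == |alt| == 1.  INS: empty ref, alt inserted *before* pos.
    DEL: empty alt, ref gives the deleted bases starting at pos.
    """

    chrom_id: str
    pos: int
    ref: str
    alt: str
    support: float

    @property
    def vtype(self) -> str:
        if self.ref and self.alt:
            return "SNP"
        return "INS" if not self.ref else "DEL"

    def __post_init__(self) -> None:
        if self.ref and self.alt and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNP calls must be single-base")
        if not self.ref and not self.alt:
            raise ValueError("call with empty ref and alt")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError(f"support {self.support} outside [0,1]")


@dataclass
class PipelineConfig:
    """Tunable constants for every stage, with the pipeline defaults."""

    stop_window_codons: int = 9
    start_window_codons: int = 9
    min_variant_support: float = 0.6
    min_homopolymer_run: int = 3
    rescue_max_rank: int = 10
    sample_count: int = 100
    genes_per_sample: int = 50
    decile_fraction: float = 0.1
    coverage_window_bp: int = 1000
    min_contig_len: int = 500
    alpha: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stop_window_codons", "start_window_codons",
                     "min_homopolymer_run", "rescue_max_rank", "sample_count",
                     "genes_per_sample", "coverage_window_bp", "min_contig_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_variant_support", "decile_fraction", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1]")


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
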