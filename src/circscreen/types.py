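"""Core domain objects shared across the pipeline.

Coordinates are 0-based, half-open throughout the package; GTF files are
converted on read/write. A circRNA is identified by its back-splice
junction ``(chrom, acceptor, donor, strand)`` where ``acceptor`` is the
genomic start of the circle (inclusive) and ``donor`` its genomic end
(exclusive), always reported in ascending genomic order with the strand
carried separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

BIOTYPES = ("protein_coding", "lincRNA", "antisense", "other_noncoding")
NONCODING_BIOTYPES = frozenset({"lincRNA", "antisense", "other_noncoding"})

#: genomic flank dinucleotides required around a circle, keyed by strand.
#: On '+' the splice acceptor AG precedes the circle start and the donor GT
#: follows its end; on '-' the transcribed-strand AG/GT rule maps to the
#: reverse complements AC (left flank) and CT (right flank) on the genome.
FLANKS_BY_STRAND = {"+": ("AG", "GT"), "-": ("AC", "CT")}


@dataclass
class GeneModel:
    """A gene with its exon structure and biotype."""

    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # sorted, non-overlapping, half-open
    biotype: str

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"exons of {self.gene_id} not sorted/disjoint")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    def introns(self) -> List[Tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]


@dataclass
class GenomeBundle:
    """A reference genome with annotation and optional rRNA sequences."""

    sequences: Dict[str, str]
    annotation: List[GeneModel]
    rrna: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene in self.annotation:
            if gene.chrom not in self.sequences:
                raise ValueError(f"{gene.gene_id} on unknown chromosome {gene.chrom}")
            if gene.end > len(self.sequences[gene.chrom]):
                raise ValueError(f"{gene.gene_id} exceeds chromosome bounds")


@dataclass
class PlantedCirc:
    """Truth record for one simulated circRNA.

    ``mean_counts`` holds the expected number of junction-spanning reads
    per library; realized counts are negative-binomial around these with
    ``variance = mean + dispersion * mean**2`` (dispersion = BCV^2).
    """

    circ_id: str
    gene_id: str
    chrom: str
    acceptor: int
    donor: int
    strand: str
    mean_counts: Dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if not self.acceptor < self.donor:
            raise ValueError("acceptor must precede donor")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    @property
    def length(self) -> int:
        return self.donor - self.acceptor


@dataclass
class LibrarySpec:
    """Parameters for one simulated sequencing library."""

    library_id: str
    condition: str  # normal | tumor
    fraction: str  # total | rnc
    n_linear_reads: int
    rrna_fraction: float = 0.0
    read_length: int = 100
    seed: int = 0
    subst_rate: float = 0.0  # optional per-base substitution rate

    def __post_init__(self) -> None:
        if not 0 <= self.rrna_fraction < 1:
            raise ValueError("rrna_fraction must lie in [0, 1)")


@dataclass
class TruthSet:
    """The simulator's ledger: what was planted and what was realized."""

    planted: List[PlantedCirc]
    read_labels: Dict[str, str]  # read_id -> linear | junction:<circ_id> | rrna
    realized_counts: Dict[Tuple[str, str], int]  # (circ_id, library_id) -> count


@dataclass
class AnchorHit:
    """Placement of one terminal anchor of an unmapped read."""

    read_id: str
    end: str  # five_prime | three_prime
    chrom: str
    pos: int
    strand: str
    unique: bool


@dataclass(frozen=True)
class BackspliceJunction:
    chrom: str
    acceptor: int
    donor: int
    strand: str
    acceptor_flank: str = "AG"  # reported on the transcribed strand
    donor_flank: str = "GT"

    @property
    def key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.acceptor, self.donor, self.strand)

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.acceptor}-{self.donor}:{self.strand}"


@dataclass
class CircCandidate:
    junction: BackspliceJunction
    support: int
    supporting_reads: Set[str] = field(default_factory=set)
    host_gene: Optional[str] = None
    host_biotype: Optional[str] = None
    origin_class: Optional[str] = None

    @property
    def length_genomic(self) -> int:
        return self.junction.donor - self.junction.acceptor

    @property
    def circ_id(self) -> str:
        return self.junction.circ_id


@dataclass
class CircRecord:
    """Per-circRNA counts and RPM values across libraries."""

    circ_id: str
    C: Dict[str, int]
    N: Dict[str, int]
    rpm: Dict[str, float] = field(default_factory=dict)


@dataclass
class DeResult:
    circ_id: str
    log2fc: float
    p: float
    q: float
    is_deg: bool


@dataclass
class Sorf:
    """A short ORF on a circular sequence (start offset in circle coords)."""

    start: int
    aa_len: int
    spans_junction: bool
    rolling: bool
    peptide: str


@dataclass
class CircularSequence:
    """Mature circle sequence, 5'->3', with the back-splice origin between
    the last and first nucleotide."""

    seq: str
    source: str = "genomic_span"  # genomic_span | exon_spliced

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("circular sequence must be non-empty")
        bad = set(self.seq) - set("ACGT")
        if bad:
            raise ValueError(f"non-DNA characters in circle: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ScreenCandidate:
    circ_id: str
    host_gene: Optional[str]
    host_biotype: Optional[str]
    de_total: DeResult
    de_rnc: DeResult
    support: int = 0
    sorfs: List[Sorf] = field(default_factory=list)
    has_ires_upstream: Optional[bool] = None
    coding_potential: Optional[bool] = None
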