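"""Synthetic study generator.

Builds a toy genome with annotated genes, plants circRNAs whose
back-splice breakpoints carry canonical AG/GT flanks on the transcribed
strand, and simulates the four-library design of a paired
transcriptome/translatome screen (two conditions x {total RNA, RNC-RNA})
plus a circle-free control library. Junction-read counts follow a
negative-binomial model with ``variance = mean + dispersion * mean**2``
(dispersion = BCV^2), the same parameterization the differential test
downstream assumes.

Everything is deterministic for a fixed seed, and every read id encodes
its truth class so the detector can be scored against the ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io
from .seqs import random_dna, revcomp
from .types import (
    FLANKS_BY_STRAND,
    GeneModel,
    GenomeBundle,
    LibrarySpec,
    PlantedCirc,
    TruthSet,
)

DEFAULT_ANCHOR = 20

STOP_CODONS = ("TAA", "TAG", "TGA")
# Codon alphabet for planted ORF bodies: no stop codons, no ATG, no codon
# that can create ATG across a codon boundary (none starts with TG or G
# after an ...AT end; none ends in AT).
_SAFE_CODONS = ["GCA", "GCC", "GAC", "GAA", "CTC", "CCT", "TCC", "AGC",
                "CGC", "GGA", "CAC", "AAG", "TTC"]


@dataclass
class SimConfig:
    """Genome- and study-level simulation parameters."""

    n_chroms: int = 3
    chrom_len: int = 35_000
    n_genes: int = 30
    n_circles: int = 20
    biotype_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.6,
            "lincRNA": 0.2,
            "antisense": 0.1,
            "other_noncoding": 0.1,
        }
    )
    exon_len_range: Tuple[int, int] = (300, 1500)
    intron_len_range: Tuple[int, int] = (100, 500)
    gene_gap_range: Tuple[int, int] = (200, 800)
    max_exons: int = 3
    circle_len_range: Tuple[int, int] = (300, 1000)
    translatable_cassette: bool = True
    cassette_len: int = 1200
    dispersion: float = 1e-4  # BCV 0.01 squared
    rrna_lens: Tuple[int, ...] = (1200, 1900)


def nb_sample(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative-binomial draw with variance mean + dispersion * mean^2."""
    if mean <= 0:
        return 0
    if dispersion == 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _atg_free_dna(rng: np.random.Generator, length: int) -> str:
    seq = list(random_dna(rng, length))
    changed = True
    while changed:
        changed = False
        for i in range(length - 2):
            if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
                seq[i + 2] = "C"
                changed = True
    return "".join(seq)


def synthetic_translatable_circle(
    seed: int,
    length: int = 1200,
    internal_aa: int = 87,
    spanning_aa: int = 69,
) -> Tuple[str, Tuple[int, int], Dict[str, Tuple[int, int]]]:
    """Design a SYNTHETIC circle emulating the sORF architecture of a
    translatable exon-derived circRNA.

    The sequence is random background carrying exactly two AUG-initiated
    short ORFs: an internal one (default 87 aa) that does not cross the
    back-splice origin, and one (default 69 aa) that wraps around it. An
    IRES-like interval is designated 478..231 nt upstream of the internal
    sORF start, mirroring where a functional IRES sits relative to the
    ORF it drives. This is a designed stand-in sequence, not a natural
    transcript.

    Returns ``(sequence, ires_interval, sorfs)`` where ``ires_interval``
    is an on-circle half-open interval and ``sorfs`` maps role ->
    ``(start, aa_len)``.
    """
    internal_nt = 3 * (internal_aa + 1)
    spanning_nt = 3 * (spanning_aa + 1)
    internal_start = length // 2
    spanning_start = length - 100
    if internal_start + internal_nt >= spanning_start:
        raise ValueError("circle too short for the requested ORF layout")
    if spanning_nt <= 100:
        raise ValueError("spanning ORF does not reach the origin")

    rng = np.random.default_rng(seed)
    seq = list(_atg_free_dna(rng, length))

    def _orf(aa_len: int) -> str:
        body = rng.choice(_SAFE_CODONS, size=aa_len - 1)
        return "ATG" + "".join(body) + "TAA"

    def _paste(start: int, cassette: str) -> None:
        for i, base in enumerate(cassette):
            seq[(start + i) % length] = base

    _paste(internal_start, _orf(internal_aa))
    _paste(spanning_start, _orf(spanning_aa))

    starts = {internal_start, spanning_start}
    bodies = []
    for s, nt in ((internal_start, internal_nt), (spanning_start, spanning_nt)):
        bodies.append({(s + i) % length for i in range(nt)})
    protected = bodies[0] | bodies[1]

    # Remove any ATG created at cassette/background boundaries.
    for _ in range(10):
        doubled = "".join(seq) + "".join(seq[:2])
        stray = [i for i in range(length) if doubled[i : i + 3] == "ATG" and i not in starts]
        if not stray:
            break
        for i in stray:
            for off in range(3):
                pos = (i + off) % length
                if pos not in protected:
                    seq[pos] = "C"
                    break
            else:  # pragma: no cover - layout guarantees a free position
                raise AssertionError("stray ATG inside protected ORF body")
    ires = (internal_start - 478, internal_start - 231)
    sorfs = {
        "internal": (internal_start, internal_aa),
        "spanning": (spanning_start, spanning_aa),
    }
    return "".join(seq), ires, sorfs


def _make_genes(rng: np.random.Generator, config: SimConfig) -> Tuple[Dict[str, bytearray], List[GeneModel]]:
    chroms = {f"chr{i + 1}": bytearray(random_dna(rng, config.chrom_len), "ascii")
              for i in range(config.n_chroms)}
    cursors = {name: 200 for name in chroms}
    names = list(chroms)
    biotypes = list(config.biotype_weights)
    weights = np.array([config.biotype_weights[b] for b in biotypes], dtype=float)
    weights /= weights.sum()

    genes: List[GeneModel] = []
    for gi in range(config.n_genes):
        if gi == 0:
            # Guaranteed lincRNA host with a single exon large enough for
            # the translatable cassette circle.
            n_exons = 1
            exon_lens = [max(config.cassette_len + 220, config.exon_len_range[1])]
            strand, biotype = "+", "lincRNA"
        else:
            n_exons = int(rng.integers(1, config.max_exons + 1))
            exon_lens = [int(rng.integers(*config.exon_len_range)) for _ in range(n_exons)]
            strand = str(rng.choice(["+", "-"]))
            biotype = str(rng.choice(biotypes, p=weights))
        intron_lens = [int(rng.integers(*config.intron_len_range)) for _ in range(n_exons - 1)]
        gap = int(rng.integers(*config.gene_gap_range))
        span = sum(exon_lens) + sum(intron_lens)

        placed = False
        for attempt in range(config.n_chroms):
            chrom = names[(gi + attempt) % config.n_chroms]
            start = cursors[chrom] + gap
            if start + span + 200 <= config.chrom_len:
                exons = []
                pos = start
                for k, elen in enumerate(exon_lens):
                    exons.append((pos, pos + elen))
                    pos += elen + (intron_lens[k] if k < n_exons - 1 else 0)
                genes.append(GeneModel(
                    gene_id=f"gene_{gi:03d}", chrom=chrom, strand=strand,
                    exons=exons, biotype=biotype,
                ))
                cursors[chrom] = start + span
                placed = True
                break
        if not placed:
            raise ValueError(
                f"genome too small: could not place gene {gi} "
                f"(need {span} nt; increase chrom_len or reduce n_genes)"
            )
    return chroms, genes


def _write_flanks(chrom_seq: bytearray, acceptor: int, donor: int, strand: str) -> None:
    left, right = FLANKS_BY_STRAND[strand]
    chrom_seq[acceptor - 2 : acceptor] = left.encode()
    chrom_seq[donor : donor + 2] = right.encode()


def make_genome(
    config: Optional[SimConfig] = None, seed: int = 0
) -> Tuple[GenomeBundle, List[PlantedCirc], Dict[str, object]]:
    """Generate the toy genome, annotation, rRNA set and planted circles.

    Returns ``(bundle, planted, info)`` where ``info`` carries the
    cassette circle's id, its IRES interval in genomic coordinates and
    the designed sORF layout (empty when no cassette is planted).
    ``mean_counts`` of the planted circles are left empty; study-level
    role assignment fills them (see :func:`simulate_study`).
    """
    config = config or SimConfig()
    if config.n_circles > config.n_genes:
        raise ValueError("n_circles must not exceed n_genes")
    rng = np.random.default_rng(seed)
    chroms, genes = _make_genes(rng, config)
    margin = 8

    planted: List[PlantedCirc] = []
    info: Dict[str, object] = {"translatable_ids": [], "ires_intervals": [], "sorfs": {}}

    host_ids: List[str] = []
    circ_idx = 0
    if config.n_circles > 0 and config.translatable_cassette:
        cassette_seed = int(rng.integers(2**31))
        cass_seq, ires_circ, sorf_layout = synthetic_translatable_circle(
            cassette_seed, length=config.cassette_len
        )
        host = genes[0]
        exon_start, exon_end = host.exons[0]
        if exon_end - exon_start < config.cassette_len + margin:
            raise ValueError(
                f"requested circle of {config.cassette_len} nt does not fit "
                f"in gene {host.gene_id}"
            )
        acceptor = exon_start + 100
        donor = acceptor + config.cassette_len
        chrom_seq = chroms[host.chrom]
        chrom_seq[acceptor:donor] = cass_seq.encode()
        _write_flanks(chrom_seq, acceptor, donor, host.strand)
        circ_id = f"circ_{circ_idx:03d}"
        planted.append(PlantedCirc(
            circ_id=circ_id, gene_id=host.gene_id, chrom=host.chrom,
            acceptor=acceptor, donor=donor, strand=host.strand,
            dispersion=config.dispersion,
        ))
        info["translatable_ids"] = [circ_id]
        info["ires_intervals"] = [
            (host.chrom, acceptor + ires_circ[0], acceptor + ires_circ[1])
        ]
        info["sorfs"] = sorf_layout
        host_ids.append(host.gene_id)
        circ_idx += 1

    remaining = [g for g in genes if g.gene_id not in host_ids]
    n_more = config.n_circles - circ_idx
    if n_more > len(remaining):
        raise ValueError("not enough genes left to host the requested circles")
    hosts = [remaining[i] for i in rng.choice(len(remaining), size=n_more, replace=False)]
    for host in hosts:
        exon_start, exon_end = max(host.exons, key=lambda e: e[1] - e[0])
        max_len = (exon_end - exon_start) - margin
        if config.circle_len_range[0] > max_len:
            raise ValueError(
                f"requested circle length >= {config.circle_len_range[0]} nt "
                f"does not fit in gene {host.gene_id}"
            )
        length = int(rng.integers(config.circle_len_range[0],
                                  min(config.circle_len_range[1], max_len) + 1))
        offset = int(rng.integers(4, (exon_end - exon_start) - length - 3))
        acceptor = exon_start + offset
        donor = acceptor + length
        _write_flanks(chroms[host.chrom], acceptor, donor, host.strand)
        planted.append(PlantedCirc(
            circ_id=f"circ_{circ_idx:03d}", gene_id=host.gene_id,
            chrom=host.chrom, acceptor=acceptor, donor=donor,
            strand=host.strand, dispersion=config.dispersion,
        ))
        circ_idx += 1

    rrna = [random_dna(rng, n) for n in config.rrna_lens]
    bundle = GenomeBundle(
        sequences={name: seq.decode() for name, seq in chroms.items()},
        annotation=genes,
        rrna=rrna,
    )
    return bundle, planted, info


def circle_sequence_of(bundle: GenomeBundle, circ: PlantedCirc) -> str:
    seq = bundle.sequences[circ.chrom][circ.acceptor : circ.donor]
    return revcomp(seq) if circ.strand == "-" else seq


def simulate_reads(
    bundle: GenomeBundle,
    planted: Sequence[PlantedCirc],
    spec: LibrarySpec,
    fastq_path=None,
    anchor: int = DEFAULT_ANCHOR,
) -> Tuple[List[Tuple[str, str]], TruthSet]:
    """Simulate one library and return ``(reads, truth_fragment)``.

    Junction reads are placed uniformly over breakpoint offsets leaving at
    least ``anchor`` nt on each side of the back-splice; linear reads are
    contiguous genomic windows drawn from gene bodies (pre-mRNA-like, so
    they always map colinearly); rRNA reads are windows of the bundled
    rRNA sequences on either strand. Read ids encode the truth class.
    """
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length
    if rl < 2 * anchor:
        raise ValueError("read_length must be at least twice the anchor length")
    for circ in planted:
        if circ.length < rl:
            raise ValueError(f"read_length exceeds circle {circ.circ_id} length")

    lib = spec.library_id
    reads: List[Tuple[str, str]] = []
    labels: Dict[str, str] = {}
    realized: Dict[Tuple[str, str], int] = {}

    for circ in planted:
        mean = circ.mean_counts.get(lib, 0.0)
        n = nb_sample(rng, mean, circ.dispersion)
        realized[(circ.circ_id, lib)] = n
        if n == 0:
            continue
        circ_seq = circle_sequence_of(bundle, circ)
        L = len(circ_seq)
        offsets = rng.integers(anchor, rl - anchor + 1, size=n)
        for i, off in enumerate(offsets):
            off = int(off)
            seq = circ_seq[L - off :] + circ_seq[: rl - off]
            read_id = f"{lib}|junc|{circ.circ_id}|{off}|{i}"
            reads.append((read_id, seq))
            labels[read_id] = f"junction:{circ.circ_id}"

    genes = bundle.annotation
    eligible = [g for g in genes if g.span >= rl]
    if spec.n_linear_reads > 0 and not eligible:
        raise ValueError("no gene long enough for linear reads")
    for i in range(spec.n_linear_reads):
        gene = eligible[int(rng.integers(len(eligible)))]
        pos = int(rng.integers(gene.start, gene.end - rl + 1))
        seq = bundle.sequences[gene.chrom][pos : pos + rl]
        if gene.strand == "-":
            seq = revcomp(seq)
        read_id = f"{lib}|linear|{i}|{gene.gene_id}"
        reads.append((read_id, seq))
        labels[read_id] = "linear"

    if spec.rrna_fraction > 0 and bundle.rrna:
        n_rrna = round(spec.n_linear_reads * spec.rrna_fraction / (1 - spec.rrna_fraction))
        for i in range(n_rrna):
            src = bundle.rrna[int(rng.integers(len(bundle.rrna)))]
            pos = int(rng.integers(0, len(src) - rl + 1))
            seq = src[pos : pos + rl]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            read_id = f"{lib}|rrna|{i}"
            reads.append((read_id, seq))
            labels[read_id] = "rrna"

    if spec.subst_rate > 0:
        alphabet = "ACGT"
        mutated = []
        for read_id, seq in reads:
            mask = rng.random(len(seq)) < spec.subst_rate
            if mask.any():
                chars = list(seq)
                for j in np.flatnonzero(mask):
                    chars[j] = alphabet[(alphabet.index(chars[j]) + int(rng.integers(1, 4))) % 4]
                seq = "".join(chars)
            mutated.append((read_id, seq))
        reads = mutated

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    if fastq_path is not None:
        io.write_fastq(fastq_path, reads)
    truth = TruthSet(planted=list(planted), read_labels=labels, realized_counts=realized)
    return reads, truth


LIBRARIES = ("normal_total", "normal_rnc", "tumor_total", "tumor_rnc")
CONTROL_LIBRARY = "control_total"


@dataclass
class StudyData:
    """Everything one simulated study produced, in memory."""

    config: SimConfig
    bundle: GenomeBundle
    planted: List[PlantedCirc]
    libraries: Dict[str, List[Tuple[str, str]]]
    truths: Dict[str, TruthSet]
    roles: Dict[str, str]
    ires_intervals: List[Tuple[str, int, int]]
    translatable_ids: List[str]
    lib_specs: Dict[str, LibrarySpec]

    def truth_counts(self) -> Dict[Tuple[str, str], int]:
        merged: Dict[Tuple[str, str], int] = {}
        for truth in self.truths.values():
            merged.update(truth.realized_counts)
        return merged


def _assign_roles(rng: np.random.Generator, planted: List[PlantedCirc],
                  genes_by_id: Dict[str, GeneModel],
                  translatable_ids: List[str]) -> Dict[str, str]:
    """Fill per-library expected junction-read counts.

    The translatome (RNC) libraries are sequenced at four-fold depth, so
    baseline RNC means are four times the total-RNA means. Differential
    roles plant eight-fold changes between conditions; up and down decoys
    are paired to keep library junction totals roughly balanced.
    """
    roles: Dict[str, str] = {}

    def set_means(circ: PlantedCirc, total_nt: Tuple[float, float], rnc_nt: Tuple[float, float]) -> None:
        circ.mean_counts = {
            "normal_total": total_nt[0], "tumor_total": total_nt[1],
            "normal_rnc": rnc_nt[0], "tumor_rnc": rnc_nt[1],
        }

    pool = []
    for circ in planted:
        if circ.circ_id in translatable_ids:
            # Down in tumor in both fractions, like a tumor-suppressive circle.
            set_means(circ, (64, 8), (256, 32))
            roles[circ.circ_id] = "translatable"
        else:
            pool.append(circ)

    coding = [c for c in pool if genes_by_id[c.gene_id].biotype == "protein_coding"]
    noncoding = [c for c in pool if genes_by_id[c.gene_id].biotype != "protein_coding"]

    def take(lst: List[PlantedCirc], n: int) -> List[PlantedCirc]:
        got = lst[:n]
        del lst[:n]
        return got

    for i, circ in enumerate(take(coding, 2)):
        t = (40, 320) if i % 2 == 0 else (320, 40)
        set_means(circ, t, (4 * t[0], 4 * t[1]))
        roles[circ.circ_id] = "de_both_coding_host"
    for circ in take(noncoding, 1):
        set_means(circ, (400, 50), (1600, 200))
        roles[circ.circ_id] = "de_both_noncoding_no_ires"
    rest = coding + noncoding
    for i, circ in enumerate(take(rest, 2)):
        t = (40, 320) if i % 2 == 0 else (320, 40)
        m = float(rng.integers(30, 61))
        set_means(circ, t, (4 * m, 4 * m))
        roles[circ.circ_id] = "de_total_only"
    for i, circ in enumerate(take(rest, 2)):
        r = (160, 1280) if i % 2 == 0 else (1280, 160)
        m = float(rng.integers(30, 61))
        set_means(circ, (m, m), r)
        roles[circ.circ_id] = "de_rnc_only"
    for circ in rest:
        mt = float(rng.integers(5, 81))
        mr = float(rng.integers(5, 81)) * 4
        set_means(circ, (mt, mt), (mr, mr))
        roles[circ.circ_id] = "null"
    return roles


def simulate_study(
    config: Optional[SimConfig] = None,
    seed: int = 0,
    outdir=None,
    n_linear_total: int = 18_000,
    n_linear_rnc: int = 72_000,
    n_linear_control: int = 20_000,
    rrna_fraction: float = 0.05,
    read_length: int = 100,
    include_control: bool = True,
) -> StudyData:
    """Simulate the full study: genome + four libraries + control.

    Library sizes default to a desk-scale rendition of the study layout
    (translatome at four-fold depth, ~200k reads overall). When
    ``outdir`` is given, genome FASTA, GTF, rRNA FASTA, per-library
    FASTQ, the truth ledger TSV and the IRES BED are written there.
    """
    config = config or SimConfig()
    bundle, planted, info = make_genome(config, seed=seed)
    genes_by_id = {g.gene_id: g for g in bundle.annotation}
    rng = np.random.default_rng(seed + 1013)
    roles = _assign_roles(rng, planted, genes_by_id, list(info["translatable_ids"]))

    specs = {}
    for k, lib in enumerate(LIBRARIES):
        condition, fraction = lib.split("_")
        specs[lib] = LibrarySpec(
            library_id=lib, condition=condition, fraction=fraction,
            n_linear_reads=n_linear_rnc if fraction == "rnc" else n_linear_total,
            rrna_fraction=rrna_fraction, read_length=read_length,
            seed=(seed + 2003 + 17 * k) % 2**31,
        )
    if include_control:
        specs[CONTROL_LIBRARY] = LibrarySpec(
            library_id=CONTROL_LIBRARY, condition="control", fraction="total",
            n_linear_reads=n_linear_control, rrna_fraction=rrna_fraction,
            read_length=read_length, seed=(seed + 90001) % 2**31,
        )

    libraries: Dict[str, List[Tuple[str, str]]] = {}
    truths: Dict[str, TruthSet] = {}
    for lib, spec in specs.items():
        reads, truth = simulate_reads(bundle, planted, spec)
        libraries[lib] = reads
        truths[lib] = truth

    study = StudyData(
        config=config, bundle=bundle, planted=planted, libraries=libraries,
        truths=truths, roles=roles,
        ires_intervals=list(info["ires_intervals"]),
        translatable_ids=list(info["translatable_ids"]),
        lib_specs=specs,
    )
    if outdir is not None:
        out = io.ensure_dir(outdir)
        io.write_fasta(out / "genome.fa", bundle.sequences)
        io.write_gtf(out / "annotation.gtf", bundle.annotation)
        io.write_fasta(out / "rrna.fa", {f"rRNA_{i+1}": s for i, s in enumerate(bundle.rrna)})
        for lib, reads in libraries.items():
            io.write_fastq(out / f"{lib}.fastq", reads)
        merged = TruthSet(
            planted=planted, read_labels={}, realized_counts=study.truth_counts()
        )
        io.write_truth_tsv(out / "truth.tsv", merged)
        with open(out / "ires.bed", "w") as fh:
            for chrom, s, e in study.ires_intervals:
                fh.write(f"{chrom}\t{s}\t{e}\tIRES\n")
    return study
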