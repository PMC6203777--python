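"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; GTF is read/written with the usual
1-based inclusive convention and converted to 0-based half-open
coordinates in memory. BED output is 0-based half-open as standard.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import CircCandidate, GeneModel

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def write_fasta(path, sequences: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: Iterable[Tuple[str, str]], quality_char: str = "I") -> None:
    """Write (read_id, sequence) pairs as Phred+33 FASTQ with flat quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> Iterator[Tuple[str, str]]:
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper()


def write_gtf(path, genes: List[GeneModel], source: str = "circscreen") -> None:
    with open(path, "w") as fh:
        for gene in genes:
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            fh.write(
                "\t".join(
                    [gene.chrom, source, "gene", str(gene.start + 1), str(gene.end),
                     ".", gene.strand, ".", attrs]
                )
                + "\n"
            )
            for exon_start, exon_end in gene.exons:
                fh.write(
                    "\t".join(
                        [gene.chrom, source, "exon", str(exon_start + 1), str(exon_end),
                         ".", gene.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_gtf(path) -> List[GeneModel]:
    """Parse exon records into gene models (needs gene_id and gene_biotype)."""
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gene_id = attrs["gene_id"]
            biotype = attrs.get("gene_biotype", "protein_coding")
            meta[gene_id] = (fields[0], fields[6], biotype)
            exons.setdefault(gene_id, []).append((int(fields[3]) - 1, int(fields[4])))
    genes = []
    for gene_id, exon_list in exons.items():
        chrom, strand, biotype = meta[gene_id]
        genes.append(
            GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                      exons=sorted(exon_list), biotype=biotype)
        )
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


CANDIDATE_BED_COLUMNS = [
    "chrom", "acceptor", "donor", "circ_id", "support", "strand",
    "host_gene", "host_biotype", "origin_class", "acceptor_flank", "donor_flank",
]


def candidates_to_frame(candidates: List[CircCandidate]) -> pd.DataFrame:
    rows = []
    for cand in candidates:
        j = cand.junction
        rows.append(
            [j.chrom, j.acceptor, j.donor, cand.circ_id, cand.support, j.strand,
             cand.host_gene or ".", cand.host_biotype or ".",
             cand.origin_class or ".", j.acceptor_flank, j.donor_flank]
        )
    return pd.DataFrame(rows, columns=CANDIDATE_BED_COLUMNS)


def write_candidates_bed(path, candidates: List[CircCandidate]) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False, header=False)


def read_bed_intervals(path) -> List[Tuple[str, int, int]]:
    """Read the first three columns of a BED file (e.g. IRES intervals)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals


def write_truth_tsv(path, truth) -> None:
    rows = []
    by_id = {c.circ_id: c for c in truth.planted}
    for (circ_id, library_id), count in sorted(truth.realized_counts.items()):
        c = by_id[circ_id]
        rows.append([circ_id, c.chrom, c.acceptor, c.donor, c.strand, library_id, count])
    pd.DataFrame(
        rows,
        columns=["circ_id", "chrom", "acceptor", "donor", "strand", "library_id",
                 "realized_count"],
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
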