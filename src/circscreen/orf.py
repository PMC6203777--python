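"""Short ORF enumeration on circular sequences.

Because translation can proceed across the back-splice origin — and, if
a frame never meets a stop codon, around the circle indefinitely — ORFs
are walked with wrap-around for up to three full passes (3L nt, which
covers every frame phase on circles whose length is not a multiple of
three). Frames that never terminate are flagged ``rolling``. Start
codons are ATG only; translation uses the standard nuclear code.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .seqs import revcomp
from .types import (
    BackspliceJunction,
    CircularSequence,
    GeneModel,
    Sorf,
)

_CODON_TO_AA: Dict[str, str] = dict(standard_dna_table.forward_table)
_STOPS = frozenset(standard_dna_table.stop_codons)


def translate(nt: str) -> str:
    """Translate an in-frame DNA string under the standard code.

    Internal stops render as ``*``; a single terminal stop is excluded
    from the returned peptide. Input length must be a multiple of three.
    """
    if len(nt) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    peptide = str(Seq(nt).translate())
    return peptide[:-1] if peptide.endswith("*") else peptide


def circular_sequence(
    junction: BackspliceJunction,
    genome: Dict[str, str],
    annotation: Optional[Sequence[GeneModel]] = None,
    mode: str = "genomic_span",
    host_gene: Optional[str] = None,
) -> CircularSequence:
    """Mature circle sequence for a called junction, 5'->3'.

    ``genomic_span`` takes the plain genomic interval (reverse
    complemented on '-'); ``exon_spliced`` concatenates the host gene's
    exons intersected with the circle, in transcription order.
    """
    chrom_seq = genome[junction.chrom]
    if mode == "genomic_span":
        seq = chrom_seq[junction.acceptor : junction.donor]
    elif mode == "exon_spliced":
        if annotation is None or host_gene is None:
            raise ValueError("exon_spliced mode needs annotation and a host gene")
        host = next((g for g in annotation if g.gene_id == host_gene), None)
        if host is None:
            raise ValueError(f"host gene {host_gene} not in annotation")
        pieces = []
        for s, e in host.exons:
            lo, hi = max(s, junction.acceptor), min(e, junction.donor)
            if lo < hi:
                pieces.append(chrom_seq[lo:hi])
        if not pieces:
            raise ValueError("circle does not overlap any host exon")
        seq = "".join(pieces)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if junction.strand == "-":
        seq = revcomp(seq)
    return CircularSequence(seq=seq, source=mode)


def find_sorfs(
    circ: CircularSequence | str,
    min_aa: int = 20,
    all_starts: bool = False,
) -> List[Sorf]:
    """Enumerate AUG-initiated sORFs of >= min_aa residues on a circle.

    Each ATG is translated forward with wrap-around until the first stop
    codon or three full passes (rolling frames). By default only the
    longest ORF per stop codon is reported (earliest start wins ties);
    ``all_starts`` also emits nested starts. Results are sorted by start
    offset.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = circ.seq if isinstance(circ, CircularSequence) else str(circ)
    L = len(seq)
    if L < 3:
        return []
    # 3L nt from any start < L, plus one codon of slack
    ext = seq * 4 + seq[:3]
    found: List[tuple] = []  # (sorf, group_key)
    roll_group = 3 if L % 3 == 0 else 1
    for p in range(L):
        if ext[p : p + 3] != "ATG":
            continue
        aa_chars: List[str] = []
        stop_at: Optional[int] = None
        for j in range(L):  # L codons == 3 full passes
            codon = ext[p + 3 * j : p + 3 * j + 3]
            if codon in _STOPS:
                stop_at = (p + 3 * j) % L
                break
            aa_chars.append(_CODON_TO_AA[codon])
        aa_len = len(aa_chars)
        if aa_len < min_aa:
            continue
        rolling = stop_at is None
        sorf = Sorf(
            start=p,
            aa_len=aa_len,
            spans_junction=(p + 3 * (aa_len + 1)) > L,
            rolling=rolling,
            peptide="".join(aa_chars),
        )
        key = ("roll", p % roll_group) if rolling else ("stop", stop_at)
        found.append((sorf, key))

    if not all_starts:
        best: Dict[tuple, Sorf] = {}
        for sorf, key in found:
            cur = best.get(key)
            if cur is None or (sorf.aa_len, -sorf.start) > (cur.aa_len, -cur.start):
                best[key] = sorf
        result = list(best.values())
    else:
        result = [sorf for sorf, _ in found]
    return sorted(result, key=lambda s: (s.start, -s.aa_len))
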