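"""Anchor-based back-splice junction detection.

The pipeline mirrors the classic split-read approach for circRNA
discovery: reads matching the rRNA set are removed; reads with a
full-length contiguous genome placement are set aside; from each
remaining read the two terminal anchors (default 20-mers) are placed on
the genome; a pair of uniquely-placed anchors in head-to-tail (reversed
genomic) order seeds a breakpoint search that extends both anchors until
the complete read is explained by two genome segments whose breakpoints
carry canonical splice flanks (AG upstream of the circle start, GT
downstream of its end, on the transcribed strand). Junctions supported
by at least two distinct read sequences become candidate circRNAs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .index import KmerIndex, Placement, build_index
from .seqs import hamming, revcomp
from .types import (
    FLANKS_BY_STRAND,
    BackspliceJunction,
    CircCandidate,
    GeneModel,
    GenomeBundle,
)

DEFAULT_ANCHOR = 20

#: outcome categories for unmapped reads; they partition the stream.
REASONS = ("called", "non_unique", "colinear", "no_gtag", "no_extension")


def filter_rrna(
    reads: Iterable[Tuple[str, str]], rrna: Sequence[str], m: int = 0, k: int = DEFAULT_ANCHOR
) -> Tuple[List[Tuple[str, str]], int]:
    """Drop reads that place full-length on any rRNA sequence.

    Returns ``(survivors, n_removed)`` with input order preserved.
    """
    reads = list(reads)
    if not rrna:
        return reads, 0
    idx = build_index({f"rRNA_{i}": s for i, s in enumerate(rrna)}, k=k)
    survivors = []
    removed = 0
    for read_id, seq in reads:
        if idx.maps_full_length(seq, m):
            removed += 1
        else:
            survivors.append((read_id, seq))
    return survivors, removed


def map_linear(
    reads: Iterable[Tuple[str, str]], index: KmerIndex, m: int = 0
) -> Tuple[List[Tuple[str, str]], List[Tuple[str, str]]]:
    """Partition reads into (mapped, unmapped) by full-length contiguous
    placement with <= m mismatches on either strand."""
    mapped, unmapped = [], []
    for read_id, seq in reads:
        (mapped if index.maps_full_length(seq, m) else unmapped).append((read_id, seq))
    return mapped, unmapped


def extract_anchors(read: str, anchor: int = DEFAULT_ANCHOR) -> Optional[Tuple[str, str]]:
    """Terminal anchors (prefix, suffix); None for reads shorter than 2A."""
    if len(read) < 2 * anchor:
        return None
    return read[:anchor], read[len(read) - anchor :]


def _extend(
    read: str,
    chrom_seq: str,
    p5: int,
    p3: int,
    anchor: int,
    m: int,
    strand: str,
) -> Tuple[Optional[BackspliceJunction], str]:
    """Breakpoint search between two head-to-tail anchor placements.

    ``read`` is in forward-genome orientation; its prefix is anchored at
    ``p5`` (donor side) and its suffix ends at ``p3 + anchor`` (acceptor
    side). Splits are scanned in ascending order so the leftmost
    acceptor satisfying both the match and the flank constraint wins.
    """
    L = len(read)
    left_flank, right_flank = FLANKS_BY_STRAND[strand]
    matched_without_flank = False
    for i in range(anchor, L - anchor + 1):
        donor = p5 + i
        acceptor = p3 + anchor - (L - i)
        if acceptor < 2 or donor + 2 > len(chrom_seq) or acceptor >= donor:
            continue
        prefix_ref = chrom_seq[p5:donor]
        suffix_ref = chrom_seq[acceptor : p3 + anchor]
        if m == 0:
            if read[:i] != prefix_ref or read[i:] != suffix_ref:
                continue
        else:
            if hamming(read[:i], prefix_ref, limit=m) > m:
                continue
            if hamming(read[i:], suffix_ref, limit=m) > m:
                continue
        if (
            chrom_seq[acceptor - 2 : acceptor] == left_flank
            and chrom_seq[donor : donor + 2] == right_flank
        ):
            return (
                BackspliceJunction(
                    chrom="", acceptor=acceptor, donor=donor, strand=strand
                ),
                "called",
            )
        matched_without_flank = True
    return None, ("no_gtag" if matched_without_flank else "no_extension")


def call_junction(
    read: str,
    hits5: Sequence[Placement],
    hits3: Sequence[Placement],
    genome: Dict[str, str],
    anchor: int = DEFAULT_ANCHOR,
    m: int = 0,
) -> Tuple[Optional[BackspliceJunction], str]:
    """Call a back-splice junction from the two anchor placements.

    Both anchors must place uniquely (exactly one best placement
    genome-wide), on the same chromosome and strand, in head-to-tail
    order; anchor pairs on different chromosomes/strands or in colinear
    order are categorized as ``colinear``. Returns ``(junction, reason)``
    with ``junction`` None unless reason is ``called``.
    """
    if len(hits5) != 1 or len(hits3) != 1:
        return None, "non_unique"
    h5, h3 = hits5[0], hits3[0]
    if h5.chrom != h3.chrom or h5.strand != h3.strand:
        return None, "colinear"
    chrom_seq = genome[h5.chrom]
    if h5.strand == "+":
        # head-to-tail: read prefix places downstream of read suffix
        if h5.pos <= h3.pos:
            return None, "colinear"
        jx, reason = _extend(read, chrom_seq, h5.pos, h3.pos, anchor, m, "+")
    else:
        # work in forward-genome orientation via the reverse complement:
        # rc(read) prefix sits where the read's 3' anchor hit, and vice versa
        if h3.pos <= h5.pos:
            return None, "colinear"
        jx, reason = _extend(revcomp(read), chrom_seq, h3.pos, h5.pos, anchor, m, "-")
    if jx is None:
        return None, reason
    return (
        BackspliceJunction(
            chrom=h5.chrom, acceptor=jx.acceptor, donor=jx.donor, strand=jx.strand
        ),
        "called",
    )


@dataclass
class JunctionCall:
    junction: BackspliceJunction
    read_id: str
    read_seq: str


@dataclass
class DetectResult:
    candidates: List[CircCandidate]
    calls: List[JunctionCall]  # every called junction read, pre-threshold
    reasons: Counter = field(default_factory=Counter)
    n_input: int = 0
    n_rrna_removed: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_short_skipped: int = 0


def collate(
    calls: Iterable[JunctionCall], min_support: int = 2
) -> List[CircCandidate]:
    """Group junction calls and emit candidates with >= min_support
    distinct supporting read sequences (PCR-duplicate-robust)."""
    grouped: Dict[tuple, Dict[str, set]] = {}
    by_key: Dict[tuple, BackspliceJunction] = {}
    for call in calls:
        key = call.junction.key
        by_key[key] = call.junction
        g = grouped.setdefault(key, {"ids": set(), "seqs": set()})
        g["ids"].add(call.read_id)
        g["seqs"].add(call.read_seq)
    out = []
    for key in sorted(grouped):
        support = len(grouped[key]["seqs"])
        if support >= min_support:
            out.append(
                CircCandidate(
                    junction=by_key[key],
                    support=support,
                    supporting_reads=set(grouped[key]["ids"]),
                )
            )
    return out


def annotate_host(
    candidates: List[CircCandidate], annotation: Sequence[GeneModel]
) -> List[CircCandidate]:
    """Assign host gene and genomic origin class in place.

    Host = same-strand gene whose span contains the circle; ties go to
    the smallest containing span, then lexicographic gene id. Origin is
    exonic when both breakpoints fall in exons of the host, intronic when
    the circle sits wholly inside one intron, antisense when only an
    opposite-strand gene contains it, intergenic otherwise.
    """
    for cand in candidates:
        j = cand.junction
        same = [
            g for g in annotation
            if g.chrom == j.chrom and g.strand == j.strand
            and g.start <= j.acceptor and j.donor <= g.end
        ]
        if same:
            host = min(same, key=lambda g: (g.span, g.gene_id))
            cand.host_gene = host.gene_id
            cand.host_biotype = host.biotype
            in_exon_a = any(s <= j.acceptor < e for s, e in host.exons)
            in_exon_d = any(s < j.donor <= e for s, e in host.exons)
            if in_exon_a and in_exon_d:
                cand.origin_class = "exonic"
            elif any(s <= j.acceptor and j.donor <= e for s, e in host.introns()):
                cand.origin_class = "intronic"
            else:
                cand.origin_class = "intergenic"
            continue
        opposite = [
            g for g in annotation
            if g.chrom == j.chrom and g.strand != j.strand
            and g.start <= j.acceptor and j.donor <= g.end
        ]
        cand.host_gene = None
        cand.host_biotype = None
        cand.origin_class = "antisense" if opposite else "intergenic"
    return candidates


SUPPORT_BINS = ("2-10", ">10")
LENGTH_BIN_WIDTH = 200
LENGTH_MAX_BIN = 1500


def summarize_catalog(
    candidates: Sequence[CircCandidate],
    length_bin_width: int = LENGTH_BIN_WIDTH,
    length_max: int = LENGTH_MAX_BIN,
) -> Dict[str, pd.Series]:
    """Catalog summaries: read-support bins, origin classes, lengths."""
    support = pd.Series(0, index=list(SUPPORT_BINS), dtype=int)
    origin = pd.Series(0, index=["exonic", "intronic", "antisense", "intergenic"], dtype=int)
    length_labels = [
        f"{lo}-{lo + length_bin_width}" for lo in range(0, length_max, length_bin_width)
    ] + [f">={length_max}"]
    length = pd.Series(0, index=length_labels, dtype=int)
    for cand in candidates:
        support["2-10" if cand.support <= 10 else ">10"] += 1
        if cand.origin_class in origin.index:
            origin[cand.origin_class] += 1
        L = cand.length_genomic
        if L >= length_max:
            length[f">={length_max}"] += 1
        else:
            lo = (L // length_bin_width) * length_bin_width
            length[f"{lo}-{lo + length_bin_width}"] += 1
    return {"support": support, "origin": origin, "length": length}


def detect_library(
    reads: Iterable[Tuple[str, str]],
    bundle: GenomeBundle,
    anchor: int = DEFAULT_ANCHOR,
    m: int = 0,
    min_support: int = 2,
    index: Optional[KmerIndex] = None,
) -> DetectResult:
    """Run the full per-library detection pipeline on a read stream."""
    reads = list(reads)
    k = anchor if m == 0 else max(1, anchor // (m + 1))
    if index is None:
        index = build_index(bundle.sequences, k=k)
    survivors, n_rrna = filter_rrna(reads, bundle.rrna, m=m, k=k)
    mapped, unmapped = map_linear(survivors, index, m=m)

    reasons: Counter = Counter()
    calls: List[JunctionCall] = []
    n_short = 0
    for read_id, seq in unmapped:
        anchors = extract_anchors(seq, anchor)
        if anchors is None:
            n_short += 1
            continue
        a5, a3 = anchors
        hits5 = index.best_hits(a5, m)
        hits3 = index.best_hits(a3, m)
        junction, reason = call_junction(seq, hits5, hits3, bundle.sequences, anchor, m)
        reasons[reason] += 1
        if junction is not None:
            calls.append(JunctionCall(junction=junction, read_id=read_id, read_seq=seq))

    candidates = collate(calls, min_support=min_support)
    annotate_host(candidates, bundle.annotation)
    return DetectResult(
        candidates=candidates,
        calls=calls,
        reasons=reasons,
        n_input=len(reads),
        n_rrna_removed=n_rrna,
        n_mapped=len(mapped),
        n_unmapped=len(unmapped),
        n_short_skipped=n_short,
    )


def quantify(
    results: Dict[str, DetectResult], min_support: int = 2
) -> pd.DataFrame:
    """Per-library junction-read counts over the union catalog.

    A circRNA enters the catalog if it reaches ``min_support`` distinct
    read sequences in at least one library; its count C in every library
    is then the number of junction reads aligned to it there (possibly
    below the calling threshold).
    """
    catalog: Dict[tuple, BackspliceJunction] = {}
    for res in results.values():
        for cand in res.candidates:
            catalog[cand.junction.key] = cand.junction
    keys = sorted(catalog)
    counts = pd.DataFrame(0, index=[catalog[k].circ_id for k in keys],
                          columns=list(results), dtype=int)
    for lib, res in results.items():
        ids: Dict[tuple, set] = {}
        for call in res.calls:
            if call.junction.key in catalog:
                ids.setdefault(call.junction.key, set()).add(call.read_id)
        for key, idset in ids.items():
            counts.loc[catalog[key].circ_id, lib] = len(idset)
    counts.index.name = "circ_id"
    return counts
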