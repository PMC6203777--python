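"""Seed-and-verify placement engine for short queries on small references.

A :class:`KmerIndex` stores every forward-strand k-mer of the reference.
Queries are placed by exact seeding of ``m + 1`` non-overlapping chunks
(pigeonhole: any full-length placement with <= m mismatches matches at
least one chunk exactly) followed by Hamming verification; reverse-strand
placements come from seeding the reverse complement. This is adequate
for the repeat-controlled toy genomes the simulator produces; it makes
no claim to genome-scale aligner performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .seqs import hamming, revcomp


@dataclass(frozen=True)
class Placement:
    chrom: str
    pos: int  # 0-based start on the forward reference
    strand: str
    mismatches: int


class KmerIndex:
    def __init__(self, sequences: Dict[str, str] | Sequence[Tuple[str, str]], k: int):
        if k < 1:
            raise ValueError("k must be positive")
        if not isinstance(sequences, dict):
            names = [name for name, _ in sequences]
            if len(names) != len(set(names)):
                raise ValueError("duplicate chromosome names")
            sequences = dict(sequences)
        self.k = k
        self.seqs = {name: seq.upper() for name, seq in sequences.items()}
        self._table: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in self.seqs.items():
            for i in range(len(seq) - k + 1):
                self._table.setdefault(seq[i : i + k], []).append((name, i))

    def _forward_hits(self, query: str, m: int) -> List[Tuple[str, int, int]]:
        k, n = self.k, len(query)
        n_chunks = min(m + 1, n // k)
        if n_chunks < m + 1:
            raise ValueError(f"query of length {n} too short for {m} mismatches with k={k}")
        candidates = set()
        for c in range(n_chunks):
            off = c * k
            for chrom, pos in self._table.get(query[off : off + k], ()):
                start = pos - off
                if start >= 0 and start + n <= len(self.seqs[chrom]):
                    candidates.add((chrom, start))
        hits = []
        for chrom, start in candidates:
            target = self.seqs[chrom][start : start + n]
            if m == 0:
                if target == query:
                    hits.append((chrom, start, 0))
            else:
                d = hamming(query, target, limit=m)
                if d <= m:
                    hits.append((chrom, start, d))
        return hits

    def find(self, query: str, m: int = 0) -> List[Placement]:
        """All placements of ``query`` on either strand with <= m mismatches."""
        out = [Placement(c, p, "+", d) for c, p, d in self._forward_hits(query, m)]
        rc = revcomp(query)
        out += [Placement(c, p, "-", d) for c, p, d in self._forward_hits(rc, m)]
        out.sort(key=lambda h: (h.mismatches, h.chrom, h.pos, h.strand))
        return out

    def best_hits(self, query: str, m: int = 0) -> List[Placement]:
        """Placements in the best (fewest-mismatch) stratum only."""
        hits = self.find(query, m)
        if not hits:
            return []
        best = hits[0].mismatches
        return [h for h in hits if h.mismatches == best]

    def maps_full_length(self, query: str, m: int = 0) -> bool:
        return bool(self.find(query, m))


def build_index(sequences: Dict[str, str] | Sequence[Tuple[str, str]], k: int) -> KmerIndex:
    return KmerIndex(sequences, k)
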