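"""The candidate funnel: doubly-differential circRNAs from non-coding
host genes, scored for coding potential.

CircRNAs called differentially expressed in both the transcriptome
(total RNA) and the translatome (RNC-RNA) contrast are intersected,
restricted to hosts annotated with a non-coding biotype (circles from
protein-coding hosts share sequence with the host ORF and cannot be
attributed cleanly), and each survivor's circle sequence is scanned for
short ORFs. Coding potential requires at least one sORF of ``min_aa``
residues and, when an IRES interval table is supplied, an IRES ending
within a configurable circular distance upstream of some sORF start.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .orf import find_sorfs
from .types import (
    NONCODING_BIOTYPES,
    CircCandidate,
    DeResult,
    ScreenCandidate,
    Sorf,
)

DEFAULT_MIN_AA = 20
DEFAULT_IRES_UPSTREAM = 500


def overlap_de(de_total: Sequence[DeResult], de_rnc: Sequence[DeResult],
               require_concordant: bool = False) -> Set[str]:
    """circRNAs differentially expressed in both contrasts.

    Direction agreement is optional (off by default).
    """
    total = {r.circ_id: r for r in de_total if r.is_deg}
    rnc = {r.circ_id: r for r in de_rnc if r.is_deg}
    ids = set(total) & set(rnc)
    if require_concordant:
        ids = {i for i in ids if total[i].log2fc * rnc[i].log2fc > 0}
    return ids


def filter_noncoding_hosts(
    ids: Iterable[str], candidates: Dict[str, CircCandidate]
) -> Tuple[List[str], int, int]:
    """Keep ids whose host gene has a non-coding biotype.

    Returns ``(kept_ids, n_coding_dropped, n_hostless_dropped)``.
    """
    kept, n_coding, n_hostless = [], 0, 0
    for circ_id in sorted(ids):
        cand = candidates.get(circ_id)
        if cand is None or cand.host_gene is None:
            n_hostless += 1
            continue
        if cand.host_biotype in NONCODING_BIOTYPES:
            kept.append(circ_id)
        else:
            n_coding += 1
    return kept, n_coding, n_hostless


def _ires_upstream_of_sorf(
    sorfs: Sequence[Sorf],
    ires_circ: Sequence[Tuple[int, int]],
    circle_len: int,
    max_upstream: int,
) -> bool:
    for sorf in sorfs:
        for _, end in ires_circ:
            dist = (sorf.start - end) % circle_len
            if dist <= max_upstream:
                return True
    return False


def assess_coding_potential(
    candidate: ScreenCandidate,
    circle_seq: Optional[str],
    min_aa: int = DEFAULT_MIN_AA,
    ires_circ: Optional[Sequence[Tuple[int, int]]] = None,
    ires_max_upstream: int = DEFAULT_IRES_UPSTREAM,
) -> ScreenCandidate:
    """Attach sORFs and the coding-potential verdict to a candidate.

    ``ires_circ`` holds IRES intervals in on-circle coordinates; None
    means no IRES evidence is available (the requirement is waived),
    while an empty list means evidence was supplied and none applies.
    """
    if circle_seq is None:
        candidate.sorfs = []
        candidate.coding_potential = None
        return candidate
    candidate.sorfs = find_sorfs(circle_seq, min_aa=min_aa)
    has_sorf = len(candidate.sorfs) > 0
    if ires_circ is None:
        candidate.has_ires_upstream = None
        candidate.coding_potential = has_sorf
    else:
        candidate.has_ires_upstream = _ires_upstream_of_sorf(
            candidate.sorfs, ires_circ, len(circle_seq), ires_max_upstream
        )
        candidate.coding_potential = has_sorf and candidate.has_ires_upstream
    return candidate


def run_screen(
    de_total: Sequence[DeResult],
    de_rnc: Sequence[DeResult],
    candidates: Sequence[CircCandidate],
    genome: Dict[str, str],
    ires_intervals: Optional[Sequence[Tuple[str, int, int]]] = None,
    min_aa: int = DEFAULT_MIN_AA,
    ires_max_upstream: int = DEFAULT_IRES_UPSTREAM,
    require_concordant: bool = False,
) -> Tuple[List[ScreenCandidate], Dict[str, int]]:
    """Run the full funnel; returns screen candidates and stage counts."""
    from .seqs import revcomp

    cand_by_id = {c.circ_id: c for c in candidates}
    de_total_by_id = {r.circ_id: r for r in de_total}
    de_rnc_by_id = {r.circ_id: r for r in de_rnc}

    ids = overlap_de(de_total, de_rnc, require_concordant=require_concordant)
    kept, n_coding, n_hostless = filter_noncoding_hosts(ids, cand_by_id)

    out: List[ScreenCandidate] = []
    for circ_id in kept:
        cand = cand_by_id[circ_id]
        j = cand.junction
        seq = genome[j.chrom][j.acceptor : j.donor]
        if j.strand == "-":
            seq = revcomp(seq)
        ires_circ = None
        if ires_intervals is not None:
            ires_circ = []
            L = j.donor - j.acceptor
            for chrom, s, e in ires_intervals:
                if chrom != j.chrom:
                    continue
                lo, hi = max(s, j.acceptor), min(e, j.donor)
                if lo >= hi:
                    continue
                if j.strand == "+":
                    ires_circ.append((lo - j.acceptor, hi - j.acceptor))
                else:
                    ires_circ.append((j.donor - hi, j.donor - lo))
        sc = ScreenCandidate(
            circ_id=circ_id,
            host_gene=cand.host_gene,
            host_biotype=cand.host_biotype,
            de_total=de_total_by_id[circ_id],
            de_rnc=de_rnc_by_id[circ_id],
            support=cand.support,
        )
        assess_coding_potential(
            sc, seq, min_aa=min_aa, ires_circ=ires_circ,
            ires_max_upstream=ires_max_upstream,
        )
        out.append(sc)

    out = rank(out)
    funnel = {
        "de_total": sum(r.is_deg for r in de_total),
        "de_rnc": sum(r.is_deg for r in de_rnc),
        "overlap": len(ids),
        "coding_host_dropped": n_coding,
        "hostless_dropped": n_hostless,
        "noncoding_host": len(kept),
        "coding_potential": sum(1 for c in out if c.coding_potential),
    }
    return out, funnel


def rank(candidates: List[ScreenCandidate]) -> List[ScreenCandidate]:
    """Deterministic ranking: coding potential first, then the smaller of
    the two q-values, then support, then circ_id."""
    return sorted(
        candidates,
        key=lambda c: (
            not bool(c.coding_potential),
            min(c.de_total.q, c.de_rnc.q),
            -c.support,
            c.circ_id,
        ),
    )


def report(candidates: List[ScreenCandidate]) -> pd.DataFrame:
    """Ranked report table (one row per screen candidate)."""
    rows = []
    for c in rank(list(candidates)):
        rows.append({
            "circ_id": c.circ_id,
            "host_gene": c.host_gene or ".",
            "host_biotype": c.host_biotype or ".",
            "support": c.support,
            "log2fc_total": c.de_total.log2fc,
            "q_total": c.de_total.q,
            "log2fc_rnc": c.de_rnc.log2fc,
            "q_rnc": c.de_rnc.q,
            "n_sorfs": len(c.sorfs),
            "sorf_aa_lens": ",".join(str(s.aa_len) for s in c.sorfs) or ".",
            "any_sorf_spans_junction": any(s.spans_junction for s in c.sorfs),
            "has_ires_upstream": c.has_ires_upstream,
            "coding_potential": c.coding_potential,
        })
    columns = ["circ_id", "host_gene", "host_biotype", "support",
               "log2fc_total", "q_total", "log2fc_rnc", "q_rnc", "n_sorfs",
               "sorf_aa_lens", "any_sorf_spans_junction", "has_ires_upstream",
               "coding_potential"]
    return pd.DataFrame(rows, columns=columns)
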