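"""Placement engine and back-splice caller: anchor placement, head-to-tail
geometry, GT/AG extension, support collation, host annotation, and the
recall/precision contract against the simulator's truth ledger."""

import pytest

from circscreen import detect
from circscreen.detect import (
    annotate_host,
    call_junction,
    collate,
    detect_library,
    extract_anchors,
    filter_rrna,
    map_linear,
    summarize_catalog,
)
from circscreen.index import build_index
from circscreen.seqs import revcomp
from circscreen.types import BackspliceJunction, CircCandidate, GeneModel, GenomeBundle
from conftest import planted_key


# ---------------------------------------------------------------- index

def test_unique_query_places_once_forward(small_study):
    chrom, seq = next(iter(small_study.bundle.sequences.items()))
    idx = build_index(small_study.bundle.sequences, k=20)
    hits = idx.find(seq[1000:1020])
    assert [(h.chrom, h.pos, h.strand) for h in hits] == [(chrom, 1000, "+")]


def test_reverse_complement_query_places_on_minus_strand(small_study):
    chrom, seq = next(iter(small_study.bundle.sequences.items()))
    idx = build_index(small_study.bundle.sequences, k=20)
    hits = idx.find(revcomp(seq[1000:1020]))
    assert [(h.chrom, h.pos, h.strand) for h in hits] == [(chrom, 1000, "-")]


def test_repeated_query_yields_two_hits():
    unit = "ACGTTGCAACGGATCCATTA"
    genome = {"c": unit + "GGGGGGGGGG" + unit}
    idx = build_index(genome, k=20)
    assert len(idx.find(unit)) == 2


def test_duplicate_chromosome_names_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        build_index([("c1", "ACGT" * 10), ("c1", "TTTT" * 10)], k=4)


def test_mismatch_placement():
    genome = {"c": "ACGTACGTGGCCATTACGGA" + "T" * 30}
    idx = build_index(genome, k=10)
    query = "ACGTACGTGGCCATTACGGA"
    mutated = query[:2] + "A" + query[3:]  # G -> A at position 2
    assert idx.find(mutated, m=0) == []
    hits = idx.find(mutated, m=1)
    assert [(h.pos, h.mismatches) for h in hits if h.strand == "+"] == [(0, 1)]


# ------------------------------------------------------------- anchors

@pytest.mark.parametrize(
    "read,anchor,expected",
    [
        ("ACGT" * 25, 20, ("ACGT" * 5, "ACGT" * 5)),
        ("A" * 39, 20, None),  # too short: skipped
        ("AC", 1, ("A", "C")),
    ],
)
def test_extract_anchors(read, anchor, expected):
    assert extract_anchors(read, anchor) == expected


# ---------------------------------------------------------- rRNA filter

def test_filter_rrna_empty_reference_is_identity(small_study):
    reads = small_study.libraries["normal_total"][:50]
    survivors, removed = filter_rrna(reads, [])
    assert survivors == reads and removed == 0


def test_read_copied_from_rrna_removed(small_study):
    rrna = small_study.bundle.rrna
    reads = [("r1", rrna[0][100:200]), ("r2", "A" * 100)]
    survivors, removed = filter_rrna(reads, rrna, m=0)
    assert removed == 1 and [r[0] for r in survivors] == ["r2"]


def test_rrna_removal_matches_truth_ledger(small_study):
    lib = "normal_total"
    truth = small_study.truths[lib]
    n_rrna_truth = sum(1 for v in truth.read_labels.values() if v == "rrna")
    _, removed = filter_rrna(small_study.libraries[lib], small_study.bundle.rrna, m=0)
    assert removed == n_rrna_truth


# ---------------------------------------------------------- linear map

def test_map_linear_partitions_by_truth(small_study):
    lib = "tumor_total"
    truth = small_study.truths[lib]
    idx = build_index(small_study.bundle.sequences, k=20)
    survivors, _ = filter_rrna(small_study.libraries[lib], small_study.bundle.rrna)
    mapped, unmapped = map_linear(survivors, idx)
    assert {rid for rid, _ in unmapped} == {
        rid for rid, label in truth.read_labels.items()
        if label.startswith("junction:")
    }
    assert all(truth.read_labels[rid] == "linear" for rid, _ in mapped)


# -------------------------------------------------------- call_junction

def _plus_circle(study):
    return next(c for c in study.planted if c.strand == "+")


def _call(study, read, anchor=20, m=0, bundle=None):
    bundle = bundle or study.bundle
    idx = build_index(bundle.sequences, k=anchor)
    a5, a3 = extract_anchors(read, anchor)
    return call_junction(read, idx.best_hits(a5, m), idx.best_hits(a3, m),
                         bundle.sequences, anchor, m)


def test_junction_read_calls_planted_coordinates(small_study):
    circ = _plus_circle(small_study)
    chrom = small_study.bundle.sequences[circ.chrom]
    read = chrom[circ.donor - 50 : circ.donor] + chrom[circ.acceptor : circ.acceptor + 50]
    junction, reason = _call(small_study, read)
    assert reason == "called"
    assert junction.key == (circ.chrom, circ.acceptor, circ.donor, "+")


def test_minus_strand_junction_read_recovered(small_study):
    circ = next(c for c in small_study.planted if c.strand == "-")
    chrom = small_study.bundle.sequences[circ.chrom]
    circ_seq = revcomp(chrom[circ.acceptor : circ.donor])
    read = circ_seq[-40:] + circ_seq[:60]
    junction, reason = _call(small_study, read)
    assert reason == "called"
    assert junction.key == (circ.chrom, circ.acceptor, circ.donor, "-")


def test_colinear_read_categorized(small_study):
    chrom = next(iter(small_study.bundle.sequences.values()))
    # anchors place in forward genomic order: not head-to-tail
    read = chrom[1000:1050] + chrom[1060:1110]
    junction, reason = _call(small_study, read)
    assert junction is None and reason == "colinear"


def test_mutated_flanks_give_no_gtag(small_study):
    circ = _plus_circle(small_study)
    sequences = dict(small_study.bundle.sequences)
    chrom = sequences[circ.chrom]
    broken = (chrom[: circ.acceptor - 2] + "TT" + chrom[circ.acceptor :])
    broken = broken[: circ.donor] + "TT" + broken[circ.donor + 2 :]
    sequences[circ.chrom] = broken
    bundle = GenomeBundle(sequences=sequences, annotation=[], rrna=[])
    read = broken[circ.donor - 50 : circ.donor] + broken[circ.acceptor : circ.acceptor + 50]
    junction, reason = _call(small_study, read, bundle=bundle)
    assert junction is None and reason == "no_gtag"


def test_nonunique_anchor_categorized():
    unit = "ACGTTGCAACGGATCCATTA"
    genome = {"c": unit + "G" * 60 + unit + "C" * 60}
    bundle = GenomeBundle(sequences=genome, annotation=[], rrna=[])
    idx = build_index(genome, k=20)
    read = unit + "G" * 20  # prefix anchor placed twice
    a5, a3 = extract_anchors(read, 20)
    junction, reason = call_junction(read, idx.best_hits(a5), idx.best_hits(a3),
                                     genome, 20, 0)
    assert junction is None and reason == "non_unique"


# -------------------------------------------------------------- collate

def _jx(acceptor=100, donor=400):
    return BackspliceJunction(chrom="c", acceptor=acceptor, donor=donor, strand="+")


def test_single_read_below_support_threshold():
    calls = [detect.JunctionCall(_jx(), "r1", "AAAA")]
    assert collate(calls) == []


def test_identical_sequences_count_once():
    calls = [detect.JunctionCall(_jx(), "r1", "AAAA"),
             detect.JunctionCall(_jx(), "r2", "AAAA")]
    assert collate(calls) == []  # PCR duplicates: support 1
    calls.append(detect.JunctionCall(_jx(), "r3", "AAAT"))
    out = collate(calls)
    assert len(out) == 1 and out[0].support == 2


# -------------------------------------------------------- annotate_host

def _gene(gene_id, strand, exons, biotype="lincRNA"):
    return GeneModel(gene_id=gene_id, chrom="c", strand=strand,
                     exons=exons, biotype=biotype)


def test_host_assignment_classes():
    genes = [
        _gene("gplus", "+", [(0, 1000)]),
        _gene("gminus", "-", [(2000, 3000)], biotype="protein_coding"),
        _gene("gintron", "+", [(4000, 4100), (4900, 5000)]),
    ]
    cands = [
        CircCandidate(junction=_jx(100, 400), support=2),
        CircCandidate(junction=BackspliceJunction("c", 2100, 2500, "+"), support=2),
        CircCandidate(junction=BackspliceJunction("c", 6000, 6400, "+"), support=2),
        CircCandidate(junction=BackspliceJunction("c", 4200, 4700, "+"), support=2),
    ]
    annotate_host(cands, genes)
    assert (cands[0].host_gene, cands[0].origin_class) == ("gplus", "exonic")
    assert cands[0].host_biotype == "lincRNA"
    assert (cands[1].host_gene, cands[1].origin_class) == (None, "antisense")
    assert (cands[2].host_gene, cands[2].origin_class) == (None, "intergenic")
    assert (cands[3].host_gene, cands[3].origin_class) == ("gintron", "intronic")


def test_host_tiebreak_smallest_span():
    genes = [
        _gene("big", "+", [(0, 5000)]),
        _gene("small", "+", [(50, 900)]),
    ]
    cands = [CircCandidate(junction=_jx(100, 400), support=2)]
    annotate_host(cands, genes)
    assert cands[0].host_gene == "small"


# ------------------------------------------------------------ summaries

def test_support_bins():
    cands = [CircCandidate(junction=_jx(), support=2),
             CircCandidate(junction=_jx(500, 2200), support=11)]
    s = summarize_catalog(cands)
    assert s["support"]["2-10"] == 1 and s["support"][">10"] == 1
    assert s["length"][">=1500"] == 1 and s["length"]["200-400"] == 1


def test_empty_catalog_summaries_are_zero():
    s = summarize_catalog([])
    assert s["support"].sum() == 0 and s["origin"].sum() == 0 and s["length"].sum() == 0


# --------------------------------------------------- pipeline contracts

def test_reason_counters_partition_unmapped(small_analysis):
    for lib, res in small_analysis.detections.items():
        assert sum(res.reasons.values()) + res.n_short_skipped == res.n_unmapped
        assert res.n_input == res.n_rrna_removed + res.n_mapped + res.n_unmapped


def test_called_junctions_satisfy_flank_invariant(small_study, small_analysis):
    from circscreen.types import FLANKS_BY_STRAND

    for res in small_analysis.detections.values():
        for cand in res.candidates:
            j = cand.junction
            seq = small_study.bundle.sequences[j.chrom]
            left, right = FLANKS_BY_STRAND[j.strand]
            assert seq[j.acceptor - 2 : j.acceptor] == left
            assert seq[j.donor : j.donor + 2] == right


def test_recall_of_planted_circles(small_study, small_analysis):
    """Every planted circle with >=2 distinct-sequence junction reads in
    some library is recovered at exact coordinates."""
    eligible = set()
    for lib, reads in small_study.libraries.items():
        offsets = {}
        for read_id, _ in reads:
            parts = read_id.split("|")
            if parts[1] == "junc":
                offsets.setdefault((lib, parts[2]), set()).add(parts[3])
        for (_, circ_id), offs in offsets.items():
            if len(offs) >= 2:
                eligible.add(circ_id)
    recovered = set()
    for res in small_analysis.detections.values():
        recovered |= {c.circ_id for c in res.candidates}
    for circ in small_study.planted:
        if circ.circ_id in eligible:
            assert planted_key(circ) in recovered


def test_no_false_candidates(small_study, small_analysis):
    planted_keys = {planted_key(c) for c in small_study.planted}
    for res in small_analysis.detections.values():
        assert {c.circ_id for c in res.candidates} <= planted_keys
    assert small_analysis.detections["control_total"].candidates == []


def test_strand_symmetry_under_genome_reflection(small_study):
    """Detection on the reverse-complemented genome mirrors every call:
    coordinates reflect and strands flip."""
    bundle = small_study.bundle
    mirrored = GenomeBundle(
        sequences={c: revcomp(s) for c, s in bundle.sequences.items()},
        annotation=[],
        rrna=bundle.rrna,
    )
    reads = [r for r in small_study.libraries["normal_total"]
             if r[0].split("|")[1] == "junc"]
    fwd = detect_library(reads, bundle)
    mir = detect_library(reads, mirrored)
    flip = {"+": "-", "-": "+"}

    def reflect(c):
        L = len(bundle.sequences[c.junction.chrom])
        return (c.junction.chrom, L - c.junction.donor, L - c.junction.acceptor,
                flip[c.junction.strand])

    assert {reflect(c) for c in mir.candidates} == {c.junction.key for c in fwd.candidates}
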