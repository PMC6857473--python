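"""Catalog model, GTF round trips, class codes vs a brute-force oracle."""

import numpy as np
import pytest

from fracseq.catalog import (
    GTFParseError,
    TranscriptCatalog,
    assembly_support,
    assign_class_code,
    intersect_assemblies,
    read_catalog,
    write_catalog,
)

from conftest import make_tx


# ---------------------------------------------------------------------------
# data model and GTF I/O


def test_transcript_invariants_rejected():
    with pytest.raises(ValueError):
        make_tx("t", [])
    with pytest.raises(ValueError):
        make_tx("t", [(100, 100)])
    with pytest.raises(ValueError):
        make_tx("t", [(100, 200), (200, 300)])  # touching exons: zero-length intron
    with pytest.raises(ValueError):
        make_tx("t", [(300, 400), (100, 200)])  # unsorted


def test_intron_chain():
    assert make_tx("t", [(100, 200), (300, 400)]).intron_chain() == ((200, 300),)
    assert make_tx("t", [(0, 50)]).intron_chain() == ()
    assert make_tx("t", [(0, 10), (20, 30), (40, 50)]).intron_chain() == (
        (10, 20),
        (30, 40),
    )


def test_gtf_coordinate_conversion(tmp_path):
    gtf = tmp_path / "a.gtf"
    attrs = 'gene_id "G1"; transcript_id "T1";'
    gtf.write_text(
        f"chr1\t.\texon\t101\t200\t.\t+\t.\t{attrs}\n"
        f"chr1\t.\texon\t301\t400\t.\t+\t.\t{attrs}\n"
    )
    catalog = read_catalog(gtf)
    assert catalog["T1"].exons == ((100, 200), (300, 400))
    assert catalog["T1"].gene_id == "G1"


def test_gtf_empty_file(tmp_path):
    gtf = tmp_path / "empty.gtf"
    gtf.write_text("")
    assert len(read_catalog(gtf)) == 0


def test_gtf_end_before_start_names_line(tmp_path):
    gtf = tmp_path / "bad.gtf"
    gtf.write_text(
        'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        'chr1\t.\texon\t400\t300\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
    )
    with pytest.raises(GTFParseError) as err:
        read_catalog(gtf)
    assert err.value.line_number == 2


def test_gtf_unknown_strand_maps_to_unknown(tmp_path):
    gtf = tmp_path / "dot.gtf"
    gtf.write_text('chr1\t.\texon\t1\t100\t.\t.\t.\tgene_id "G"; transcript_id "T";\n')
    assert read_catalog(gtf)["T"].strand == "."


def test_gtf_round_trip(tmp_path, simple_reference):
    path = tmp_path / "rt.gtf"
    write_catalog(simple_reference, path)
    back = read_catalog(path)
    assert sorted(back.transcript_ids) == sorted(simple_reference.transcript_ids)
    for tid in back.transcript_ids:
        assert back[tid].exons == simple_reference[tid].exons
        assert back[tid].strand == simple_reference[tid].strand


# ---------------------------------------------------------------------------
# class codes


def _oracle_class_code(query, reference):
    """Brute-force base-set oracle for the class-code decision.

    Works on explicit integer base sets and junction tuples derived directly
    from exon lists, independent of the interval arithmetic under test.
    """

    def exon_bases(t):
        return {b for s, e in t.exons for b in range(s, e)}

    def introns(t):
        return [
            (t.exons[i][1], t.exons[i + 1][0]) for i in range(len(t.exons) - 1)
        ]

    q_introns = introns(query)
    q_bases = exon_bases(query)
    q_span = set(range(query.exons[0][0], query.exons[-1][1]))
    refs = [r for r in reference if r.chrom == query.chrom]
    same = [r for r in refs if r.strand == query.strand]
    opp = [r for r in refs if r.strand not in (query.strand, ".")]

    if any(introns(r) == q_introns and len(r.exons) > 1 for r in same):
        return "="
    for r in same:
        ri = introns(r)
        n = len(q_introns)
        contiguous = any(ri[i : i + n] == q_introns for i in range(len(ri) - n + 1)) and n > 0
        r_span = set(range(r.exons[0][0], r.exons[-1][1]))
        if contiguous and q_span <= r_span:
            return "c"
    if any(set(introns(r)) & set(q_introns) for r in same):
        return "j"
    for r in refs:
        for s, e in introns(r):
            if q_span <= set(range(s, e)):
                return "i"
    same_overlap = any(exon_bases(r) & q_bases for r in same)
    opp_overlap = any(exon_bases(r) & q_bases for r in opp)
    if opp_overlap and not same_overlap:
        return "x"
    if same_overlap:
        return "o"
    return "u"


CODE_CASES = [
    # identical intron chain, terminal ends differ -> "="
    (make_tx("q=", [(50, 200), (300, 400), (500, 650)], "+"), "="),
    # contiguous sub-chain of R5 within its span -> "c"
    (make_tx("qc", [(5150, 5300), (5400, 5450)], "+"), "c"),
    # shares R1's first junction only -> "j"
    (make_tx("qj", [(100, 200), (300, 350), (420, 480)], "+"), "j"),
    # entirely inside R2's intron -> "i"
    (make_tx("qi", [(1300, 1400), (1500, 1600)], "+"), "i"),
    # overlaps R3's exons on the opposite strand -> "x"
    (make_tx("qx", [(3050, 3150), (3250, 3350)], "+"), "x"),
    # same-strand exonic overlap with mono-exonic R4, no junctions -> "o"
    (make_tx("qo", [(3900, 4100), (4200, 4300)], "+"), "o"),
    # overlaps nothing -> "u"
    (make_tx("qu", [(9000, 9100), (9200, 9300)], "+"), "u"),
]


@pytest.mark.parametrize("query,expected", CODE_CASES, ids=[c[1] for c in CODE_CASES])
def test_class_code_geometries(simple_reference, query, expected):
    assert assign_class_code(query, simple_reference) == expected
    assert _oracle_class_code(query, simple_reference) == expected


def test_class_code_unknown_strand_rejected(simple_reference):
    q = make_tx("q", [(100, 200), (300, 400)], ".")
    with pytest.raises(ValueError):
        assign_class_code(q, simple_reference)


def test_class_code_matches_oracle_on_random_geometries(simple_reference):
    """Totality/exclusivity: random small geometries agree with the oracle."""
    rng = np.random.default_rng(2024)
    for _ in range(300):
        n_exons = int(rng.integers(2, 5))
        pos = int(rng.integers(0, 6000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(20, 250))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(10, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        q = make_tx("q", exons, strand)
        got = assign_class_code(q, simple_reference)
        assert got == _oracle_class_code(q, simple_reference)
        assert got in ("=", "c", "j", "i", "x", "o", "u")


# ---------------------------------------------------------------------------
# intersection and support


def test_intersect_idempotent(simple_reference):
    out = intersect_assemblies(simple_reference, simple_reference)
    assert sorted(out.transcript_ids) == sorted(simple_reference.transcript_ids)


def test_intersect_disjoint():
    a = TranscriptCatalog([make_tx("a", [(0, 100), (200, 300)])])
    b = TranscriptCatalog([make_tx("b", [(5000, 5100), (5200, 5300)])])
    assert len(intersect_assemblies(a, b)) == 0


def test_intersect_terminal_ends_ignored():
    a = TranscriptCatalog([make_tx("a1", [(100, 200), (300, 400)])])
    b = TranscriptCatalog([make_tx("b1", [(50, 200), (300, 450)])])
    out = intersect_assemblies(a, b)
    assert out.transcript_ids == ["a1"]  # keeps a's identifier


def test_intersect_subset_and_symmetry(small_study):
    a, b = small_study.assembled, small_study.reference
    ab = intersect_assemblies(a, b)
    ba = intersect_assemblies(b, a)
    assert set(ab.transcript_ids) <= set(a.transcript_ids)
    # membership symmetric up to identifier choice: same chain keys
    assert ab.chain_keys() == ba.chain_keys()


def test_assembly_support_counts():
    t = make_tx("t", [(100, 200), (300, 400)])
    containing = TranscriptCatalog([make_tx("s", [(80, 200), (300, 420)])])
    empty = TranscriptCatalog()
    catalogs = [(containing, "tumor")] * 3 + [(empty, "tumor")] * 2 + [(empty, "adjacent")] * 5
    s = assembly_support(t, catalogs)
    assert (s.tumor_support, s.adjacent_support) == (3, 0)
    s0 = assembly_support(make_tx("z", [(7000, 7100), (7200, 7300)]), catalogs)
    assert (s0.tumor_support, s0.adjacent_support) == (0, 0)


def test_assembly_support_monotone():
    t = make_tx("t", [(100, 200), (300, 400)])
    containing = TranscriptCatalog([make_tx("s", [(100, 200), (300, 400)])])
    base = [(TranscriptCatalog(), "tumor"), (containing, "adjacent")]
    before = assembly_support(t, base)
    after = assembly_support(t, base + [(containing, "tumor")])
    assert after.tumor_support >= before.tumor_support
    assert after.adjacent_support >= before.adjacent_support
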