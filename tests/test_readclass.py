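import pytest

from runjkit.genemodel import GeneModel, Transcript
from runjkit import readclass as R
from runjkit.variants import SpliceEvent, SpliceVariant, annotate_event


def read(cigar, start, qname="r1", mapq=60):
    ops = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5}
    out, n = [], ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            out.append((ops[ch], int(n)))
            n = ""
    return R.AlignedRead(qname=qname, ref_start=start, cigar=tuple(out), mapq=mapq)


@pytest.fixture(scope="module")
def gm():
    # exons (1-based): 801-1000, 1201-1400, 1801-2000; introns (1000,1200), (1400,1800)
    tx = Transcript("t", "G", "chr1", "+",
                    ((800, 1000), (1200, 1400), (1800, 2000)), canonical=True)
    return GeneModel.from_transcripts([tx])


def make_event(gm, event_type, site_pos):
    v = SpliceVariant(
        chrom="chr1", pos=site_pos, ref="C", alt="T", gene="G",
        ds_ag=0.0, ds_al=0.0, ds_dg=0.0, ds_dl=0.0,
        dp_ag=0, dp_al=0, dp_dg=0, dp_dl=0,
    )
    e = SpliceEvent(v, event_type, 0.9, site_pos)
    return annotate_event(e, gm)


# ---------------------------------------------------------------------------
# CIGAR geometry
# ---------------------------------------------------------------------------

def test_junctions_pure_match():
    assert R.junctions_of(read("101M", 100)) == []


def test_junction_hand_walked():
    (j,) = R.junctions_of(read("50M200N51M", 100))
    assert (j.donor_end, j.acceptor_start) == (150, 350)


def test_two_junctions():
    js = R.junctions_of(read("30M100N30M100N41M", 0))
    assert [(j.donor_end, j.acceptor_start) for j in js] == [(30, 130), (160, 260)]


def test_deletions_do_not_make_junctions():
    assert R.junctions_of(read("50M10D50M", 100)) == []
    blocks = R.aligned_blocks(read("50M10D50M", 100))
    assert blocks == [(100, 150), (160, 210)]


def test_ref_end_includes_skip():
    assert read("50M200N50M", 100).ref_end == 400


# ---------------------------------------------------------------------------
# Read retrieval
# ---------------------------------------------------------------------------

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def sam_line(qname, pos1, cigar, mapq=60, flag=0):
    length = sum(
        int(n) for n, op in _cigar_pairs(cigar) if op in "MIS"
    )
    return (f"{qname}\t{flag}\tchr1\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t"
            f"{'A' * length}\t*\n")


def _cigar_pairs(cigar):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield n, ch
            n = ""


def test_reads_crossing_filters(tmp_path):
    p = 1001  # 1-based
    sam = tmp_path / "t.sam"
    sam.write_text(
        SAM_HEADER
        + sam_line("span", p - 50, "101M")          # crosses by alignment
        + sam_line("lowq", p - 50, "101M", mapq=19)  # below MapQ cutoff
        + sam_line("gap", p - 40, "50M200N50M")      # N gap spans p
        + sam_line("before", p - 300, "101M")        # ends upstream of p
        + sam_line("dup", p - 50, "101M", flag=1024)  # duplicate-marked
    )
    got = {r.qname for r in R.reads_crossing(str(sam), "chr1", p)}
    assert got == {"span", "gap"}


def test_reads_crossing_absent_contig_empty(tmp_path):
    sam = tmp_path / "t.sam"
    sam.write_text(SAM_HEADER + sam_line("r", 100, "50M"))
    assert R.reads_crossing(str(sam), "chrZ", 1000) == []


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def test_dl_retention_is_abnormal_direct(gm):
    e = make_event(gm, "DL", 1000)
    r = read("101M", 949)  # aligned bases on both sides of the boundary
    assert R.classify_direct(r, e, gm).call == "abnormal_direct"


def test_dl_canonical_junction_is_normal(gm):
    e = make_event(gm, "DL", 1000)
    r = read("50M200N51M", 950)  # junction (1000, 1200) = canonical intron
    assert R.classify_direct(r, e, gm).call == "normal"
    assert R.classify_all(r, e, gm).call == "normal"


def test_ag_novel_junction_is_abnormal_direct(gm):
    # novel acceptor: first exonic base at 1196 -> junction resumes at 0-based 1195
    e = make_event(gm, "AG", 1196)
    r = read("40M195N60M", 960)  # junction (1000, 1195)
    assert R.junctions_of(r)[0].acceptor_start == 1195
    assert R.classify_direct(r, e, gm).call == "abnormal_direct"


def test_ag_contiguous_and_canonical_are_normal(gm):
    e = make_event(gm, "AG", 1196)
    assert R.classify_all(read("100M", 1150), e, gm).call == "normal"
    r = read("50M200N50M", 950)  # canonical junction spans p
    assert R.classify_all(r, e, gm).call == "normal"


def test_dl_cryptic_junction_abnormal_only_under_all(gm):
    e = make_event(gm, "DL", 1000)
    # cryptic donor 10 bases inside the exon: junction (990, 1200)
    r = read("40M210N60M", 950)
    assert R.classify_all(r, e, gm).call == "abnormal_other"
    assert R.classify_direct(r, e, gm).call == "uninformative"


def test_exon_skip_is_abnormal_under_all(gm):
    e = make_event(gm, "AL", 1201)
    r = read("40M800N60M", 960)  # junction (1000, 1800): skips exon 2 entirely
    assert R.classify_all(r, e, gm).call == "abnormal_other"


def test_soft_clip_at_decision_point_uninformative(gm):
    e = make_event(gm, "DL", 1000)
    r = read("52M48S", 950)  # aligned end at 1002, clipped 2bp past the boundary
    assert R.classify_all(r, e, gm).call == "uninformative"
    assert R.classify_direct(r, e, gm).call == "uninformative"


def test_minus_strand_mirror_classification():
    # mirror of the plus-strand model around the interval midpoint
    tx = Transcript("t", "G", "chr1", "-",
                    ((800, 1000), (1200, 1400), (1800, 2000)), canonical=True)
    gm = GeneModel.from_transcripts([tx])
    e = make_event(gm, "DL", 1201)  # donor = genomic start of middle exon
    retention = read("101M", 1150)  # spans 1200/1201 boundary
    canonical = read("50M200N51M", 950)
    assert R.classify_direct(retention, e, gm).call == "abnormal_direct"
    assert R.classify_direct(canonical, e, gm).call == "normal"


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def calls(spec):
    return [R.ReadCall(q, c) for q, c in spec]


def test_count_excludes_uninformative():
    cs = calls(
        [(f"a{i}", "abnormal_direct") for i in range(12)]
        + [(f"n{i}", "normal") for i in range(88)]
        + [(f"u{i}", "uninformative") for i in range(5)]
    )
    assert R.count_reads(cs, "all") == (12, 88)
    assert R.count_reads([], "all") == (0, 0)


def test_mates_counted_once_and_conflict_is_abnormal():
    cs = calls([("r", "abnormal_direct"), ("r", "abnormal_direct")])
    assert R.count_reads(cs, "all") == (1, 0)
    cs = calls([("r", "abnormal_direct"), ("r", "normal")])
    assert R.count_reads(cs, "all") == (1, 0)
    cs = calls([("r", "uninformative"), ("r", "normal")])
    assert R.count_reads(cs, "all") == (0, 1)


def test_direct_mode_excludes_other_abnormal():
    cs = calls([("a", "abnormal_direct"), ("b", "abnormal_other"), ("c", "normal")])
    assert R.count_reads(cs, "direct") == (1, 1)
    assert R.count_reads(cs, "all") == (2, 1)


def test_direct_abnormal_never_exceeds_all():
    cs = calls(
        [("a", "abnormal_direct"), ("b", "abnormal_other"), ("c", "abnormal_other"),
         ("d", "normal"), ("e", "uninformative")]
    )
    assert R.count_reads(cs, "direct")[0] <= R.count_reads(cs, "all")[0]


def test_bad_mode_raises():
    with pytest.raises(ValueError):
        R.count_reads([], "both")
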