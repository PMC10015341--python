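import textwrap

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from runjkit.genemodel import GeneModel, Transcript
from runjkit import variants as V
from runjkit.synthetic import simulate_spliceai_vcf, toy_gene_model


def make_variant(ds_ag=0.0, ds_al=0.0, ds_dg=0.0, ds_dl=0.0, pos=1000,
                 consequence="missense", **kw):
    return V.SpliceVariant(
        chrom="chr1", pos=pos, ref="C", alt="T", gene="G",
        ds_ag=ds_ag, ds_al=ds_al, ds_dg=ds_dg, ds_dl=ds_dl,
        dp_ag=kw.get("dp_ag", 0), dp_al=kw.get("dp_al", 0),
        dp_dg=kw.get("dp_dg", 0), dp_dl=kw.get("dp_dl", 0),
        original_consequence=consequence,
    )


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------

VCF_TEMPLATE = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr17,length=10000000>
    ##INFO=<ID=SpliceAI,Number=.,Type=String,Description="dialect">
    ##INFO=<ID=Consequence,Number=1,Type=String,Description="csq">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
    """)


def write_vcf(tmp_path, body):
    p = tmp_path / "in.vcf"
    p.write_text(VCF_TEMPLATE + body)
    return str(p)


def test_parse_direct_field_mapping(tmp_path):
    path = write_vcf(
        tmp_path,
        "chr17\t7675000\t.\tG\tA\t.\t.\t"
        "SpliceAI=A|TP53|0.02|0.91|0.00|0.03|12|-1|3|5;Consequence=synonymous\n",
    )
    (v,) = V.parse_spliceai_vcf(path)
    assert (v.gene, v.ds_al, v.dp_al) == ("TP53", 0.91, -1)
    assert (v.ds_ag, v.dp_ag, v.ds_dl, v.dp_dl) == (0.02, 12, 0.03, 5)
    assert v.original_consequence == "synonymous"


def test_parse_skips_unannotated_records(tmp_path, caplog):
    path = write_vcf(
        tmp_path,
        "chr17\t100\t.\tG\tA\t.\t.\tConsequence=missense\n"
        "chr17\t200\t.\tG\tA\t.\t.\tSpliceAI=A|TP53|0.1|0|0|0|1|0|0|0\n",
    )
    with caplog.at_level("INFO", logger="runjkit.variants"):
        vs = V.parse_spliceai_vcf(path)
    assert len(vs) == 1
    assert "skipped 1" in caplog.text


def test_parse_multiallelic_two_annotations(tmp_path):
    path = write_vcf(
        tmp_path,
        "chr17\t300\t.\tG\tA,C\t.\t.\t"
        "SpliceAI=A|TP53|0.1|0|0|0|1|0|0|0,C|TP53|0.2|0|0|0|2|0|0|0\n",
    )
    vs = V.parse_spliceai_vcf(path)
    assert [v.alt for v in vs] == ["A", "C"]
    assert [v.ds_ag for v in vs] == [0.1, 0.2]


def test_parse_malformed_entry_warns_not_fatal(tmp_path, caplog):
    path = write_vcf(
        tmp_path,
        "chr17\t400\t.\tG\tA\t.\t.\tSpliceAI=A|TP53|bad\n"
        "chr17\t500\t.\tG\tA\t.\t.\tSpliceAI=A|TP53|0.6|0|0|0|1|0|0|0\n",
    )
    with caplog.at_level("WARNING"):
        vs = V.parse_spliceai_vcf(path)
    assert len(vs) == 1 and "malformed" in caplog.text


def test_parse_missing_file_fatal(tmp_path):
    with pytest.raises(OSError):
        V.parse_spliceai_vcf(str(tmp_path / "nope.vcf"))


# ---------------------------------------------------------------------------
# Event selection
# ---------------------------------------------------------------------------

def test_select_strongest_score():
    e = V.select_top_event(make_variant(ds_ag=0.10, ds_al=0.80, ds_dg=0.05))
    assert (e.event_type, e.ds) == ("AL", 0.80)


def test_select_all_zero_returns_none():
    assert V.select_top_event(make_variant()) is None


def test_select_tie_break_order():
    e = V.select_top_event(make_variant(ds_ag=0.6, ds_al=0.6, ds_dg=0.1, ds_dl=0.1))
    assert e.event_type == "AL"
    e = V.select_top_event(make_variant(ds_dg=0.6, ds_ag=0.6))
    assert e.event_type == "AG"
    e = V.select_top_event(make_variant(ds_dl=0.5, ds_dg=0.5))
    assert e.event_type == "DL"


def test_site_pos_uses_matching_offset():
    e = V.select_top_event(make_variant(ds_dl=0.9, dp_dl=-7, dp_ag=99))
    assert e.site_pos == 1000 - 7


@given(
    ds=st.tuples(*[st.floats(0, 1, allow_nan=False)] * 4),
    thr=st.floats(0, 1, allow_nan=False),
)
@settings(derandomize=True, max_examples=100)
def test_filter_significant_properties(ds, thr):
    v = make_variant(ds_ag=ds[0], ds_al=ds[1], ds_dg=ds[2], ds_dl=ds[3])
    e = V.select_top_event(v)
    events = [e] if e else []
    kept = V.filter_significant(events, thr)
    # idempotent, monotone, boundary-inclusive
    assert V.filter_significant(kept, thr) == kept
    assert set(V.filter_significant(events, min(1.0, thr + 0.1))) <= set(kept)
    assert all(x.ds >= thr for x in kept)


def test_filter_boundary_inclusive():
    evs = [
        V.SpliceEvent(make_variant(ds_dl=d), "DL", d, 1000)
        for d in (0.49, 0.50, 0.90)
    ]
    assert [e.ds for e in V.filter_significant(evs)] == [0.50, 0.90]
    assert V.filter_significant([], 0.5) == []


# ---------------------------------------------------------------------------
# Relative positions
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gm_anchor():
    # plus-strand gene: exon [801,1000], intron, exon [2001,2200] (1-based)
    tx = Transcript("t", "G", "chr1", "+", ((800, 1000), (2000, 2200)))
    return GeneModel.from_transcripts([tx])


def rel_of(gm, pos, event_type, gene="G"):
    v = make_variant(ds_dl=0.9, pos=pos)
    e = V.SpliceEvent(v, event_type, 0.9, pos)
    rp = V.relative_position(v, e, gm)
    return rp.rel if rp else None


def test_donor_last_exonic_base_is_zero(gm_anchor):
    assert rel_of(gm_anchor, 1000, "DL") == 0


def test_donor_fifth_intronic_base(gm_anchor):
    assert rel_of(gm_anchor, 1005, "DL") == 5


def test_acceptor_third_intronic_upstream(gm_anchor):
    # acceptor = first exonic base 2001; 1998 is the 3rd intronic base upstream
    assert rel_of(gm_anchor, 1998, "AL") == -3


def test_acceptor_has_no_zero(gm_anchor):
    assert rel_of(gm_anchor, 2001, "AL") == 1
    assert rel_of(gm_anchor, 2000, "AL") == -1


def test_gene_absent_is_unresolvable(gm_anchor):
    v = make_variant(ds_dl=0.9, pos=1000)
    v = V.SpliceVariant(**{**v.__dict__, "gene": "OTHER"})
    e = V.SpliceEvent(v, "DL", 0.9, 1000)
    assert V.relative_position(v, e, gm_anchor) is None


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("event_type,rels", [
    ("DL", [0, 5, -2]),
    ("AG", [-15, -3, 1, 3]),
])
def test_relative_position_round_trip_both_strands(tmp_path, strand, event_type, rels):
    """Simulated variants at requested offsets map back to the same offsets."""
    gm = toy_gene_model(strand=strand)
    vcf = simulate_spliceai_vcf(
        gm,
        [{"event_type": event_type, "ds": 0.9, "rel": r} for r in rels],
        str(tmp_path / "e.vcf"),
    )
    vs = V.parse_spliceai_vcf(vcf)
    got = sorted(
        V.relative_position(v, V.annotate_event(V.select_top_event(v), gm), gm).rel
        for v in vs
    )
    assert got == sorted(rels)


def test_position_spectrum_normalizes_per_type(gm_anchor):
    evs = []
    for pos, et in [(1000, "DL")] * 3 + [(1005, "DL")] + [(1998, "AL")] * 2:
        v = make_variant(ds_dl=0.9, pos=pos)
        evs.append(V.SpliceEvent(v, et, 0.9, pos))
    df = V.position_spectrum(evs, gm_anchor)
    dl = df[df.event_type == "DL"].set_index("rel")
    assert dl.loc[0, "count"] == 3 and dl.loc[0, "fraction"] == 0.75
    assert df.groupby("event_type")["fraction"].sum().round(9).eq(1).all()
    assert V.position_spectrum([], gm_anchor).empty


# ---------------------------------------------------------------------------
# Reclassification and gene frequencies
# ---------------------------------------------------------------------------

def test_reclassify_rules():
    assert V.reclassify(make_variant(ds_dl=0.91, consequence="synonymous")) == "splice"
    assert V.reclassify(make_variant(ds_dl=0.30, consequence="missense")) == "missense"
    assert V.reclassify(make_variant(ds_dl=0.10, consequence="splice_donor")) == "splice"


def test_reclassify_never_unsplices_and_counts_match():
    vs = [
        make_variant(ds_dl=d, consequence=c)
        for d, c in [(0.9, "missense"), (0.2, "missense"), (0.6, "synonymous"),
                     (0.0, "splice_donor"), (0.55, "splice_acceptor")]
    ]
    out = [V.reclassify(v) for v in vs]
    assert out == ["splice", "missense", "splice", "splice", "splice"]
    n_converted = sum(
        1 for v, o in zip(vs, out)
        if o == "splice" and v.original_consequence.lower() not in V.ESSENTIAL_SPLICE_CATEGORIES
    )
    n_expected = sum(
        1 for v in vs
        if v.max_ds >= 0.5 and v.original_consequence.lower() not in V.ESSENTIAL_SPLICE_CATEGORIES
    )
    assert n_converted == n_expected == 2


def test_gene_splice_frequency():
    rows = []
    for s in ("s1", "s2", "s3"):
        rows.append((s, "G", "splice_donor", "splice"))
    for s in ("s4", "s5"):
        rows.append((s, "G", "synonymous", "splice"))  # cryptic
    rows.append(("s1", "G", "synonymous", "splice"))  # same sample: no double count
    rows.append(("s6", "H", "missense", "missense"))
    df = pd.DataFrame(rows, columns=["sample", "gene", "consequence",
                                     "reclassified_consequence"])
    out = V.gene_splice_frequency(df, ["G", "H", "ABSENT"], cohort_size=100)
    g = out.set_index("gene")
    assert g.loc["G", "freq_essential"] == 0.03
    assert g.loc["G", "freq_with_cryptic"] == 0.05
    assert g.loc["ABSENT"].tolist() == [0.0, 0.0]
    assert (out.freq_with_cryptic >= out.freq_essential).all()
    assert V.gene_splice_frequency(df, [], 100).empty
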