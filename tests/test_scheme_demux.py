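import os

import pytest

from ampligeno._util import ReadRecord, read_fastq, revcomp
from ampligeno.scheme_demux import (
    DEFAULT_M13,
    IndexEntry,
    LocusDef,
    PrimerScheme,
    SchemeError,
    demultiplex_read_pair,
    demux_stream,
    load_scheme,
    match_prefix,
    write_scheme,
)
from ampligeno.synthetic import default_config, simulate_reads, simulate_true_genotypes


def small_scheme():
    return PrimerScheme(
        loci=[
            LocusDef("locA", "GAATTCTAGGTAGACTGTAG", "CAGCGATGGCTGTCTGTAGT"),
            LocusDef("locB", "GAGACATAGCGGACGATTGT", "CGCAAGAGCCTTCCTGGAGG"),
        ],
        samples=[
            IndexEntry("s1", "AAAACCCCGG", "TTGA"),
            IndexEntry("s2", "TTTTGGGGCC", "TTGA"),
            IndexEntry("s3", "ACGTACGTAC", "TTGA"),
        ],
    )


def test_scheme_tsv_roundtrip(tmp_path):
    scheme = small_scheme()
    path = tmp_path / "scheme.tsv"
    write_scheme(scheme, path)
    loaded = load_scheme(path)
    assert loaded.locus_names == ["locA", "locB"]
    assert loaded.sample_names == ["s1", "s2", "s3"]
    assert loaded.m13 == DEFAULT_M13


def test_scheme_validation_errors():
    with pytest.raises(SchemeError, match="duplicate index"):
        PrimerScheme(
            loci=[LocusDef("l", "GAATTCTAGGTAGACTGTAG", "CAGCGATGGCTGTCTGTAGT")],
            samples=[
                IndexEntry("a", "AAAACCCCGG", "TTGA"),
                IndexEntry("b", "AAAACCCCGG", "TTGA"),
            ],
        )
    with pytest.raises(SchemeError, match="index must be 10"):
        IndexEntry("a", "AAAACCCCG", "TTGA")
    with pytest.raises(SchemeError, match="duplicate locus"):
        PrimerScheme(
            loci=[
                LocusDef("l", "GAATTCTAGGTAGACTGTAG", "CAGCGATGGCTGTCTGTAGT"),
                LocusDef("l", "GAGACATAGCGGACGATTGT", "CGCAAGAGCCTTCCTGGAGG"),
            ],
            samples=[IndexEntry("a", "AAAACCCCGG", "TTGA")],
        )


def test_match_prefix_resolution():
    cands = [("a", "ACGTACGT"), ("b", "ACGTACCA")]
    assert match_prefix("ACGTACGTTTTT", cands, 1) == ("a", "ok")
    assert match_prefix("GGGGGGGGGGGG", cands, 1) == (None, "none")
    # equidistant from both patterns -> ambiguous (brute-force distances 1, 1)
    seq = "ACGTACGA" + "TTTT"
    d = [sum(x != y for x, y in zip(seq, p)) for _, p in cands]
    assert d == [1, 1]
    assert match_prefix(seq, cands, 1) == (None, "ambiguous")


def _build_pair(scheme, sample, locus, insert, read_len=120):
    entry = next(s for s in scheme.samples if s.sample == sample)
    ld = next(l for l in scheme.loci if l.name == locus)
    prefix = entry.protective + entry.index + scheme.m13
    construct = prefix + ld.fwd_primer + insert + revcomp(ld.rev_primer) + revcomp(prefix)
    r1 = construct[:read_len]
    r2 = revcomp(construct)[:read_len]
    return (
        ReadRecord("p", r1, "I" * len(r1)),
        ReadRecord("p", r2, "I" * len(r2)),
    )


def test_demultiplex_roundtrip_and_trimming():
    scheme = small_scheme()
    insert = "ACGGATTACGGATTAGCCGGTTAACCGGCCATAT"
    r1, r2 = _build_pair(scheme, "s2", "locB", insert)
    res = demultiplex_read_pair(r1, r2, scheme)
    assert (res.sample, res.locus, res.reason) == ("s2", "locB", "ok")
    assert res.r1.seq == insert
    assert res.r2.seq == revcomp(insert)


def test_demultiplex_mismatch_tolerances():
    scheme = small_scheme()
    insert = "ACGGATTACGGATTAGCCGGTTAACCGGCCATAT"
    r1, r2 = _build_pair(scheme, "s1", "locA", insert)
    # two index errors exceed index_mm=1
    seq = list(r1.seq)
    seq[4], seq[5] = "T", "T"  # index starts after 4 protective bases
    broken = ReadRecord(r1.id, "".join(seq), r1.qual)
    seq2 = list(r2.seq)
    seq2[4], seq2[5] = "C", "C"
    broken2 = ReadRecord(r2.id, "".join(seq2), r2.qual)
    res = demultiplex_read_pair(broken, broken2, scheme, index_mm=1)
    assert res.reason == "no_index" and res.sample == "UNASSIGNED"
    # one primer mismatch is tolerated at primer_mm=2
    seq = list(r1.seq)
    pos = 4 + 10 + len(scheme.m13) + 3
    seq[pos] = {"A": "C"}.get(seq[pos], "A")
    res = demultiplex_read_pair(ReadRecord(r1.id, "".join(seq), r1.qual), r2, scheme, primer_mm=2)
    assert (res.sample, res.locus, res.reason) == ("s1", "locA", "ok")


def test_flipped_pair_is_normalised():
    scheme = small_scheme()
    insert = "ACGGATTACGGATTAGCCGGTTAACCGGCCATAT"
    r1, r2 = _build_pair(scheme, "s3", "locA", insert)
    res = demultiplex_read_pair(r2, r1, scheme)  # mates swapped
    assert (res.sample, res.locus, res.reason) == ("s3", "locA", "ok")
    assert res.r1.seq == insert  # forward primer leads mate 1 again


def _simulate(tmp_path, seed, **kw):
    cfg = default_config(seed=seed, **kw)
    truth = simulate_true_genotypes(cfg)
    paths = simulate_reads(cfg, truth, tmp_path / "sim")
    return cfg, truth, paths


def test_demux_stream_partitions_input(tmp_path):
    cfg, _, paths = _simulate(
        tmp_path, 41, n_samples=6, n_loci=3, depth_mean=40, error_rate=0.005
    )
    from ampligeno.scheme_demux import load_scheme

    scheme = load_scheme(paths["scheme"])
    counts = demux_stream(paths["r1"], paths["r2"], scheme, tmp_path / "demux")
    assert counts["pairs"].sum() == paths["n_pairs"]
    ok = counts[counts["reason"] == "ok"]
    # simulated read ids encode the true (sample, locus): no read may
    # land in another sample's bin, and nearly all are assigned
    for name in os.listdir(tmp_path / "demux"):
        if name.endswith(".R1.fastq") and "__" in name:
            sample, locus = name[: -len(".R1.fastq")].split("__")
            for rec in read_fastq(tmp_path / "demux" / name):
                true_sample, true_locus, _ = rec.id.split("_")
                assert true_sample == sample
                assert true_locus == locus
    assert ok["pairs"].sum() >= 0.99 * paths["n_pairs"]


def test_demux_stream_deterministic(tmp_path):
    cfg, _, paths = _simulate(
        tmp_path, 43, n_samples=4, n_loci=2, depth_mean=25, error_rate=0.005
    )
    from ampligeno.scheme_demux import load_scheme

    scheme = load_scheme(paths["scheme"])
    demux_stream(paths["r1"], paths["r2"], scheme, tmp_path / "d1")
    demux_stream(paths["r1"], paths["r2"], scheme, tmp_path / "d2")
    files1 = sorted(os.listdir(tmp_path / "d1"))
    assert files1 == sorted(os.listdir(tmp_path / "d2"))
    for name in files1:
        b1 = (tmp_path / "d1" / name).read_bytes()
        b2 = (tmp_path / "d2" / name).read_bytes()
        assert b1 == b2, name


def test_demux_stream_empty_inputs(tmp_path):
    r1 = tmp_path / "empty1.fastq"
    r2 = tmp_path / "empty2.fastq"
    r1.write_text("")
    r2.write_text("")
    counts = demux_stream(r1, r2, small_scheme(), tmp_path / "out")
    assert len(counts) == 0


def test_demux_stream_mate_mismatch_is_fatal(tmp_path):
    r1 = tmp_path / "a.fastq"
    r2 = tmp_path / "b.fastq"
    r1.write_text("@x\nACGT\n+\nIIII\n")
    r2.write_text("")
    with pytest.raises(IOError):
        demux_stream(r1, r2, small_scheme(), tmp_path / "out")
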