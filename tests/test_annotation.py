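import io

import numpy as np
import pytest

from spliceret import annotation
from spliceret.annotation import (
    GeneModel,
    GeneModelSet,
    GtfParseError,
    MissingChromosomeError,
    boundary_motifs,
    extract_boundaries,
    filter_min_flank,
    filter_safe,
    parse_gene_models,
    structure_profile,
)

from conftest import make_boundary, random_model_set


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_boundaries(models):
    """Enumerate consecutive-exon gaps, dedup by coordinates."""
    seen = {}
    for g in models.genes:
        for exons in g.transcripts.values():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 > e1:
                    seen.setdefault((g.chrom, e1, s2, g.strand), []).append(g.gene_id)
    return seen


def brute_force_safe_keys(models):
    """Interval-overlap oracle: intron vs every exon, nested loops."""
    exons = list(models.all_exons())
    out = set()
    for key in brute_force_boundaries(models):
        chrom, istart, iend, strand = key
        hit = False
        for echrom, es, ee in exons:
            if echrom == chrom and es < iend and ee > istart:
                hit = True
                break
        if not hit:
            out.add(key)
    return out


# ---------------------------------------------------------------------------
# parse_gene_models

GTF_ONE_TX = (
    'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";\n'
    'chr1\tx\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";\n'
)


def test_parse_coordinate_convention():
    models = parse_gene_models(io.StringIO(GTF_ONE_TX))
    assert len(models) == 1
    assert models.genes[0].transcripts["g1.t1"] == [(0, 100), (200, 300)]


def test_parse_empty_stream():
    models = parse_gene_models(io.StringIO(""))
    assert len(models) == 0


def test_parse_duplicate_exon_lines_collapse():
    models = parse_gene_models(io.StringIO(GTF_ONE_TX + GTF_ONE_TX))
    assert models.genes[0].transcripts["g1.t1"] == [(0, 100), (200, 300)]


def test_parse_malformed_line_names_line_number():
    with pytest.raises(GtfParseError, match="line 2"):
        parse_gene_models(io.StringIO(GTF_ONE_TX.splitlines()[0] + "\nbroken line\n"))


def test_parse_end_before_start_rejected():
    bad = 'chr1\tx\texon\t300\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
    with pytest.raises(GtfParseError, match="end < start"):
        parse_gene_models(io.StringIO(bad))


def test_parse_non_exon_features_ignored():
    text = 'chr1\tx\tCDS\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";\n' + GTF_ONE_TX
    models = parse_gene_models(io.StringIO(text))
    assert models.genes[0].transcripts["g1.t1"] == [(0, 100), (200, 300)]


def test_parse_roundtrip_against_generator_truth(fixture_world, fixture_paths):
    models = parse_gene_models(fixture_paths["annotation"])
    truth = {g.gene_id: g for g in fixture_world.models.genes}
    assert set(g.gene_id for g in models.genes) == set(truth)
    for g in models.genes:
        assert g.strand == truth[g.gene_id].strand
        assert g.transcripts == truth[g.gene_id].transcripts


# ---------------------------------------------------------------------------
# extract_boundaries

def test_single_two_exon_transcript_one_boundary():
    models = parse_gene_models(io.StringIO(GTF_ONE_TX))
    bs = extract_boundaries(models)
    assert len(bs) == 1
    b = bs[0]
    assert (b.intron_start, b.intron_end) == (100, 200)
    assert b.intron_len == 100
    assert b.donor_pos == 100 and b.acceptor_pos == 200


def test_shared_intron_deduplicated():
    g = GeneModel("g", "chr1", "+", {
        "t1": [(0, 100), (200, 300)],
        "t2": [(50, 100), (200, 350)],
    })
    bs = extract_boundaries(GeneModelSet([g]))
    assert len(bs) == 1
    # flanking exon lengths: minimum across sharing transcripts
    assert bs[0].upstream_exon_len == 50
    assert bs[0].downstream_exon_len == 100


def test_intronless_transcript_contributes_nothing():
    g = GeneModel("g", "chr1", "+", {"t1": [(0, 500)]})
    assert extract_boundaries(GeneModelSet([g])) == []


def test_minus_strand_flank_orientation():
    g = GeneModel("g", "chr1", "-", {"t1": [(0, 80), (200, 350)]})
    b = extract_boundaries(GeneModelSet([g]))[0]
    # transcript-sense upstream exon is the genomic-right one
    assert b.upstream_exon_len == 150
    assert b.downstream_exon_len == 80
    assert b.donor_pos == 199 and b.acceptor_pos == 79
    assert b.donor_pos - b.acceptor_pos == b.intron_len


def test_boundaries_match_brute_force_on_random_fixtures():
    rng = np.random.default_rng(42)
    for _ in range(30):
        models = random_model_set(rng, n_genes=8)
        bs = extract_boundaries(models)
        oracle = brute_force_boundaries(models)
        assert {b.key for b in bs} == set(oracle)


# ---------------------------------------------------------------------------
# filter_safe

def test_nested_gene_exon_removes_host_boundary():
    host = GeneModel("host", "chr1", "+", {"t1": [(0, 100), (500, 600)]})
    nested = GeneModel("nested", "chr1", "-", {"t1": [(200, 300)]})
    models = GeneModelSet([host, nested])
    bs = extract_boundaries(models)
    assert len(bs) == 1
    assert filter_safe(bs, models) == []


def test_isolated_gene_keeps_all_boundaries():
    g = GeneModel("g", "chr1", "+", {"t1": [(0, 100), (200, 300), (400, 500)]})
    models = GeneModelSet([g])
    bs = extract_boundaries(models)
    safe = filter_safe(bs, models)
    assert len(safe) == len(bs) == 2
    assert all(b.safe for b in safe)


def test_alternative_donor_removes_overlapped_boundary():
    g = GeneModel("g", "chr1", "+", {
        "t1": [(0, 100), (300, 400)],     # intron [100, 300)
        "t2": [(0, 150), (300, 400)],     # exon extends 50 nt into t1's intron
    })
    models = GeneModelSet([g])
    bs = extract_boundaries(models)
    assert len(bs) == 2
    safe = filter_safe(bs, models)
    keys = {b.key for b in safe}
    assert ("chr1", 100, 300, "+") not in keys  # overlapped by t2's exon
    assert ("chr1", 150, 300, "+") in keys


def test_filter_safe_matches_brute_force_and_is_idempotent():
    rng = np.random.default_rng(7)
    for _ in range(30):
        models = random_model_set(rng, n_genes=8)
        bs = extract_boundaries(models)
        safe = filter_safe(bs, models)
        assert {b.key for b in safe} == brute_force_safe_keys(models)
        again = filter_safe(safe, models)
        assert {b.key for b in again} == {b.key for b in safe}
        assert len(safe) <= len(bs)


def test_generator_truth_unsafe_boundaries_removed(default_world, default_world_paths):
    models = parse_gene_models(default_world_paths["annotation"])
    bs = extract_boundaries(models)
    safe_keys = {b.key for b in filter_safe(bs, models)}
    for bt in default_world.truth.boundaries:
        if bt.unsafe:
            assert bt.key not in safe_keys
    assert any(bt.unsafe for bt in default_world.truth.boundaries)


# ---------------------------------------------------------------------------
# filter_min_flank

@pytest.mark.parametrize(
    "intron_len,up,down,kept",
    [
        (49, 100, 100, False),
        (50, 100, 100, True),
        (100, 49, 100, False),
        (100, 50, 50, True),
        (100, 100, 49, False),
    ],
)
def test_min_flank_threshold_inclusivity(intron_len, up, down, kept):
    b = make_boundary(intron_start=1000, intron_end=1000 + intron_len, up=up, down=down)
    assert (filter_min_flank([b], 50) == [b]) is kept


def test_min_flank_zero_is_identity():
    rng = np.random.default_rng(0)
    bs = [
        make_boundary(intron_start=s, intron_end=s + int(l), up=int(u), down=int(d))
        for s, l, u, d in zip(
            range(0, 10000, 1000),
            rng.integers(1, 800, 10),
            rng.integers(1, 300, 10),
            rng.integers(1, 300, 10),
        )
    ]
    assert filter_min_flank(bs, 0) == bs


def test_min_flank_matches_brute_force():
    rng = np.random.default_rng(3)
    bs = [
        make_boundary(intron_start=s, intron_end=s + int(l), up=int(u), down=int(d))
        for s, l, u, d in zip(
            range(0, 50000, 500),
            rng.integers(1, 200, 100),
            rng.integers(1, 200, 100),
            rng.integers(1, 200, 100),
        )
    ]
    expect = [
        b
        for b in bs
        if b.intron_len >= 50 and b.upstream_exon_len >= 50 and b.downstream_exon_len >= 50
    ]
    assert filter_min_flank(bs, 50) == expect


# ---------------------------------------------------------------------------
# structure_profile

def test_intronless_genes_profile_is_100_everywhere():
    genes = [
        GeneModel(f"g{i}", "chr1", "+", {"t1": [(0, 1000 + 37 * i)]})
        for i in range(20)
    ]
    prof = structure_profile(GeneModelSet(genes), n_segments=1000)
    assert np.all(prof.freq == 100.0)
    assert prof.n_genes == 20


def test_half_covered_gene():
    # gene span pinned by a terminal 1 nt exon; first half exonic
    g = GeneModel("g", "chr1", "+", {"t1": [(0, 500), (999, 1000)]})
    prof = structure_profile(GeneModelSet([g]), n_segments=10)
    assert list(prof.freq) == [100.0] * 5 + [0.0] * 4 + [100.0]


def test_minus_strand_gene_is_flipped():
    g = GeneModel("g", "chr1", "-", {"t1": [(0, 100), (900, 1000)]})
    prof = structure_profile(GeneModelSet([g]), n_segments=10)
    # genomic-right exon (100 nt) is the transcript 5' end -> segment 0
    assert list(prof.freq) == [100.0, 0, 0, 0, 0, 0, 0, 0, 0, 100.0]


def test_short_genes_skipped_with_warning(caplog):
    g_short = GeneModel("tiny", "chr1", "+", {"t1": [(0, 50)]})
    g_long = GeneModel("big", "chr1", "+", {"t1": [(0, 2000)]})
    with caplog.at_level("WARNING"):
        prof = structure_profile(GeneModelSet([g_short, g_long]), n_segments=100)
    assert prof.n_genes == 1 and prof.n_skipped == 1
    assert "tiny" in caplog.text


def test_empty_model_set_errors():
    with pytest.raises(ValueError):
        structure_profile(GeneModelSet([]), 10)


def test_structure_profile_matches_per_base_oracle():
    rng = np.random.default_rng(12)
    n_seg = 50
    models = random_model_set(rng, n_genes=40)
    keep = [g for g in models.genes if g.span()[1] - g.span()[0] >= n_seg]
    models = GeneModelSet(keep)
    prof = structure_profile(models, n_segments=n_seg)
    # oracle: rasterize per base, group bases by segment index, any()
    counts = np.zeros(n_seg)
    for g in models.genes:
        s0, e0 = g.span()
        length = e0 - s0
        cov = np.zeros(length, dtype=bool)
        for exons in g.transcripts.values():
            for s, e in exons:
                cov[s - s0 : e - s0] = True
        if g.strand == "-":
            cov = cov[::-1]
        for seg in range(n_seg):
            if any(cov[i] for i in range(length) if i * n_seg // length == seg):
                counts[seg] += 1
    np.testing.assert_allclose(prof.freq, 100.0 * counts / len(models.genes))


# ---------------------------------------------------------------------------
# boundary_motifs

def _genome_with_introns(intron_dinucs):
    """One + strand gene per requested intron dinucleotide pair."""
    chrom_parts = []
    boundaries = []
    pos = 0
    rng = np.random.default_rng(5)
    for i, (donor, acceptor) in enumerate(intron_dinucs):
        exon1 = "".join(rng.choice(list("ACGT"), 30))
        intron = donor + "".join(rng.choice(list("ACGT"), 26)) + acceptor
        exon2 = "".join(rng.choice(list("ACGT"), 30))
        start = pos
        chrom_parts.append(exon1 + intron + exon2)
        boundaries.append(
            make_boundary(
                chrom="chrM",
                intron_start=start + 30,
                intron_end=start + 60,
                up=30,
                down=30,
                gene_id=f"g{i}",
            )
        )
        pos += 90
    return {"chrM": "".join(chrom_parts)}, boundaries


def test_canonical_gt_ag_gives_full_ic_at_dinucleotides():
    genome, bs = _genome_with_introns([("GT", "AG")] * 12)
    donor, acceptor = boundary_motifs(genome, bs, left_flank=3, right_flank=6)
    assert donor.n_sequences == 12 and donor.n_dropped == 0
    # intronic positions +1, +2 are matrix columns 3 and 4
    g_row, t_row = 2, 3
    assert donor.counts[g_row, 3] == 12 and donor.counts[t_row, 4] == 12
    np.testing.assert_allclose(donor.info_content[3], 2.0)
    np.testing.assert_allclose(donor.info_content[4], 2.0)
    # acceptor window: 6 intronic + 3 exonic; AG at columns 4, 5
    a_row = 0
    assert acceptor.counts[a_row, 4] == 12 and acceptor.counts[g_row, 5] == 12
    np.testing.assert_allclose(acceptor.info_content[4], 2.0)


def test_single_sequence_has_ic_2_everywhere():
    genome, bs = _genome_with_introns([("GT", "AG")])
    donor, _ = boundary_motifs(genome, bs)
    np.testing.assert_allclose(donor.info_content, 2.0)


def test_noncanonical_fraction_matches_counts():
    specs = [("GT", "AG")] * 18 + [("CA", "AG")] * 2
    genome, bs = _genome_with_introns(specs)
    donor, _ = boundary_motifs(genome, bs)
    g_row, t_row, c_row, a_row = 2, 3, 1, 0
    assert donor.counts[g_row, 3] == 18 and donor.counts[c_row, 3] == 2
    assert donor.counts[t_row, 4] == 18 and donor.counts[a_row, 4] == 2


def test_motif_column_sums_constant():
    genome, bs = _genome_with_introns([("GT", "AG")] * 7)
    donor, acceptor = boundary_motifs(genome, bs)
    assert set(donor.counts.sum(axis=0)) == {7}
    assert set(acceptor.counts.sum(axis=0)) == {7}


def test_non_acgt_sequences_dropped_and_counted():
    genome, bs = _genome_with_introns([("GT", "AG")] * 3)
    seq = genome["chrM"]
    genome["chrM"] = seq[:31] + "N" + seq[32:]  # inside first donor window
    donor, _ = boundary_motifs(genome, bs)
    assert donor.n_sequences == 2 and donor.n_dropped == 1


def test_missing_chrom_raises_naming_it():
    _, bs = _genome_with_introns([("GT", "AG")])
    with pytest.raises(MissingChromosomeError, match="chrM"):
        boundary_motifs({"other": "ACGT" * 100}, bs)


def test_minus_strand_motif_reverse_complemented():
    # one - strand intron: transcript-sense GT..AG means genomic CT..AC
    rng = np.random.default_rng(9)
    exon1 = "".join(rng.choice(list("ACGT"), 30))
    intron = "CT" + "".join(rng.choice(list("ACGT"), 26)) + "AC"
    exon2 = "".join(rng.choice(list("ACGT"), 30))
    genome = {"chrM": exon1 + intron + exon2}
    b = make_boundary(chrom="chrM", strand="-", intron_start=30, intron_end=60, up=30, down=30)
    donor, acceptor = boundary_motifs(genome, [b])
    g_row, t_row, a_row = 2, 3, 0
    assert donor.counts[g_row, 3] == 1 and donor.counts[t_row, 4] == 1
    assert acceptor.counts[a_row, 4] == 1 and acceptor.counts[g_row, 5] == 1
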