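import numpy as np
import pytest

from spliceret.annotation import GeneModel, GeneModelSet, SpliceBoundary
from spliceret.simulate import (
    SimConfig,
    generate_world,
    recovery_config,
    worked_fixture_config,
)


@pytest.fixture(scope="session")
def fixture_world():
    """The miniature deterministic world (3 genes, 4 boundaries)."""
    return generate_world(worked_fixture_config(read_seed=7))


@pytest.fixture(scope="session")
def fixture_paths(fixture_world, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return fixture_world.write(str(outdir))


@pytest.fixture(scope="session")
def default_world():
    return generate_world(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_world_paths(default_world, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("default_world")
    return default_world.write(str(outdir))


@pytest.fixture(scope="session")
def recovery_world_small():
    """Single-intron world: 10 boundaries per retention level, 300 frags."""
    return generate_world(
        recovery_config(boundaries_per_level=10, fragments_per_boundary=300, seed=11)
    )


def make_boundary(
    intron_start=250,
    intron_end=450,
    strand="+",
    chrom="chr1",
    gene_id="gA",
    up=150,
    down=150,
    safe=True,
):
    return SpliceBoundary(
        chrom=chrom,
        strand=strand,
        intron_start=intron_start,
        intron_end=intron_end,
        gene_id=gene_id,
        upstream_exon_len=up,
        downstream_exon_len=down,
        safe=safe,
    )


def random_model_set(rng: np.random.Generator, n_genes=6) -> GeneModelSet:
    """Small random gene models for property tests (not via the simulator)."""
    genes = []
    cursor = 10
    for gi in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(f"g{gi}", "chrP", strand, {})
        n_tx = int(rng.integers(1, 4))
        n_exons = int(rng.integers(1, 5))
        # exon skeleton shared by transcripts, with random per-transcript tweaks
        lens = rng.integers(20, 120, size=2 * n_exons - 1)
        coords = []
        pos = cursor
        for i in range(n_exons):
            coords.append((pos, pos + int(lens[2 * i])))
            pos += int(lens[2 * i])
            if i < n_exons - 1:
                pos += int(lens[2 * i + 1])
        for t in range(n_tx):
            exons = list(coords)
            if t > 0 and n_exons > 1 and rng.random() < 0.5:
                # drop a random internal exon (exon-skipping isoform)
                drop = int(rng.integers(0, n_exons))
                exons = [e for i, e in enumerate(exons) if i != drop]
            if exons:
                gene.transcripts[f"t{t}"] = exons
        if gene.transcripts:
            genes.append(gene)
        cursor = pos + int(rng.integers(10, 200))
    return GeneModelSet(genes)
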