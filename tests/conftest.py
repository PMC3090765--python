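import pytest

from mapscaffold import io, pipeline
from mapscaffold.simulator import SimConfig, simulate_fixture


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default simulated assembly: ~10 Mb over 2 chromosomes,
    ~300 contigs, small gaps bridgeable by the sequence libraries."""
    out = tmp_path_factory.mktemp("simfix")
    return simulate_fixture(SimConfig(seed=20260920), out)


@pytest.fixture(scope="session")
def default_links(default_fixture):
    """All links (map + sequence) extracted from the default fixture."""
    fix = default_fixture
    lengths = io.read_contig_lengths(fix.contigs_fasta)
    map_links, map_libs, map_skips = pipeline.map_to_links(
        fix.map_tsv, fix.marker_psl, lengths)
    seq_specs = {lib.name: pipeline.sequence_library(lib.name, lib.insert_mean)
                 for lib in fix.config.libraries}
    seq_links, seq_skips = pipeline.sam_to_links(fix.sam_paths, seq_specs)
    return {
        "lengths": lengths,
        "map_links": map_links, "map_libs": map_libs, "map_skips": map_skips,
        "seq_links": seq_links, "seq_skips": seq_skips,
        "seq_specs": seq_specs,
        "all_libs": list(seq_specs.values()) + map_libs,
    }
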