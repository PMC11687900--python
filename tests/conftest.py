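import pytest

from stopshift.synthdata import SynthConfig, run_synth, simulate_genome


SMALL = dict(genes_per_genome=60, n_orthogroups=5, mean_gene_len_codons=120,
             reassigned_codon_family_usage=0.15, suppressor_trna=True,
             telomere_cap=True)


@pytest.fixture(scope="session")
def small_bundle_dirs(tmp_path_factory):
    """Tiny written bundles (<=5 orthogroups) for tables 1, 15 and 16."""
    root = tmp_path_factory.mktemp("bundles")
    dirs = {}
    for tid in (1, 15, 16):
        cfg = SynthConfig(seed=100 + tid, query_table_id=tid, **SMALL)
        out = root / f"table{tid}"
        run_synth(cfg, out)
        dirs[tid] = out
    return dirs


@pytest.fixture(scope="session")
def pipeline_bundle_dir(tmp_path_factory):
    """A richer written table-16 bundle for end-to-end pipeline tests."""
    cfg = SynthConfig(seed=77, query_table_id=16, genes_per_genome=120,
                      n_orthogroups=60, reassigned_codon_family_usage=0.12,
                      suppressor_trna=True, telomere_cap=True)
    out = tmp_path_factory.mktemp("pipeline") / "table16"
    run_synth(cfg, out)
    return out


@pytest.fixture(scope="session")
def table16_bundle():
    """An in-memory table-16 genome bundle shared across read-only tests."""
    cfg = SynthConfig(seed=42, query_table_id=16, genes_per_genome=120,
                      n_orthogroups=40, reassigned_codon_family_usage=0.1)
    return simulate_genome(cfg)
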