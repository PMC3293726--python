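import pytest

from utrsnp.io_formats import read_alignments, read_fasta
from utrsnp.pileup import build_pileup
from utrsnp.simulate import SimConfig, simulate_reads, simulate_truth, write_all
from utrsnp.snp_caller import call_snps


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Noise-free planted-haplotype dataset: 20 contigs x 2 kb, depth 20,
    balanced haplotypes, fixed seed.  Shared across tests as the recovery
    substrate."""
    cfg = SimConfig(
        n_contigs=20,
        contig_length_range=(2000, 2000),
        depth=20.0,
        minor_haplotype_fraction=0.5,
        substitution_error_rate=0.0,
        seed=0,
    )
    truth = simulate_truth(cfg)
    readset = simulate_reads(truth, cfg)
    paths = write_all(readset, tmp_path_factory.mktemp("sim"))
    return cfg, truth, readset, paths


@pytest.fixture(scope="session")
def sim_pipeline(sim_bundle):
    """The sim bundle pushed through SAM ingestion, pileup and SNP calling."""
    cfg, truth, readset, paths = sim_bundle
    contigs = read_fasta(paths["contigs"])
    reads = list(read_alignments(paths["sam"], contigs, samples=cfg.samples))
    pile = build_pileup(reads, contigs)
    snps = call_snps(pile, contigs)
    return contigs, reads, pile, snps
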