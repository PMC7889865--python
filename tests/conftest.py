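import numpy as np
import pytest

from phasembly.pipeline import run_pipeline
from phasembly.sim import SimConfig, SVSpec, simulate


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A 300 kb diploid library at the default coverage operating point."""
    kwargs = dict(
        genome_length=300_000,
        n_barcodes=1_500,
        molecules_per_barcode=1,
        molecule_mean_length=30_000,
        base_error_rate=0.0,
        seed=seed,
        sv_spec=[
            SVSpec("DEL", 300, "het"),
            SVSpec("INS", 120, "hom"),
            SVSpec("DEL", 80, "hom"),
            SVSpec("INS", 250, "het"),
        ],
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_run(small_sim):
    cfg = small_sim.truth.cfg
    read_based = [(cfg.chrom, v.pos, v.ref_allele, v.alt_allele, "het")
                  for v in small_sim.het_variants]
    return run_pipeline(
        small_sim.alignments, small_sim.het_variants,
        small_sim.truth.ref_seq, cfg.chrom, read_based=read_based,
    )


@pytest.fixture(scope="session")
def acceptance_sim():
    """The 1 Mb error-free study condition used by the acceptance checks."""
    cfg = SimConfig(
        seed=1,
        base_error_rate=0.0,
        sv_spec=[
            SVSpec("DEL", 300, "het"), SVSpec("INS", 120, "hom"),
            SVSpec("DEL", 80, "het"), SVSpec("INS", 250, "het"),
            SVSpec("DEL", 150, "hom"), SVSpec("INS", 60, "hom"),
        ],
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def acceptance_run(acceptance_sim):
    cfg = acceptance_sim.truth.cfg
    read_based = [(cfg.chrom, v.pos, v.ref_allele, v.alt_allele, "het")
                  for v in acceptance_sim.het_variants]
    return run_pipeline(
        acceptance_sim.alignments, acceptance_sim.het_variants,
        acceptance_sim.truth.ref_seq, cfg.chrom, read_based=read_based,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
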