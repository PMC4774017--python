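import numpy as np
import pytest

from varbench.synthetic import SimConfig, expected_metrics, generate
from varbench.varcomp import classify


def compact_config(seed: int = 5, **overrides) -> SimConfig:
    """A reduced-scale study configuration used across the suite so the full
    pipeline runs in seconds; planted rates and error modes keep their
    defaults."""
    cfg = SimConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length=220_000,
        segment_size=(300, 1200),
        n_genes=30,
        exon_length=(150, 260),
        intron_length=(150, 450),
        acmg_size=5,
        clinvar_omim_size=10,
        n_gc_windows=6,
        repeat_classes={
            "SINE": (25, 120, 350),
            "LINE": (6, 400, 1200),
            "low_complexity": (6, 60, 200),
        },
        stratum_counts={
            "non-synonymous": 100,
            "synonymous": 100,
            "truncating": 20,
            "splicing": 15,
            "intergenic": 400,
        },
        n_mnv_pairs=10,
        n_false_positives=20,
        n_systematic_sites=15,
        n_subthreshold_sites=6,
        n_lowqual_sites=2,
        n_db_decoys=5,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def bundle():
    return generate(compact_config())


@pytest.fixture(scope="session")
def expected(bundle):
    return expected_metrics(bundle)


@pytest.fixture(scope="session")
def match(bundle):
    return classify(bundle.query, bundle.truth, bundle.hiconf, bundle.reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_reference(rng, length: int = 400, chrom: str = "chr1") -> dict:
    return {chrom: "".join("ACGT"[i] for i in rng.integers(0, 4, length))}
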