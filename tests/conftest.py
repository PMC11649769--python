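import numpy as np
import pytest

import screenkit as sk


@pytest.fixture(scope="session")
def two_line_config():
    return sk.SimConfig(
        n_target_genes=80,
        essential_fraction=0.125,
        n_preferential=4,
        cell_lines=("ref", "mut"),
        replicates_per_line=3,
        sequencing_depth=500_000,
        seed=123,
    )


@pytest.fixture(scope="session")
def two_line_screen(two_line_config):
    """A small simulated two-line screen taken through normalization."""
    cfg = two_line_config
    library = sk.generate_library(cfg)
    truth = sk.generate_truth(library, cfg)
    counts, meta = sk.simulate_screen_counts(library, truth, cfg)
    factors = sk.ntc_size_factors(counts, library)
    fc = sk.quantile_normalize(sk.shrna_log_fold_change(counts, factors))
    return {
        "config": cfg,
        "library": library,
        "truth": truth,
        "counts": counts,
        "meta": meta,
        "factors": factors,
        "fc": fc,
    }


@pytest.fixture(scope="session")
def expression_fixture():
    cfg = sk.ExpressionSimConfig(
        n_genes=300,
        cells_per_group=40,
        signature_sizes={"sig3": 40, "neu": 30, "mono": 30},
        effects={("sig3", "URE"): 1.0, ("neu", "URE"): 1.0},
        seed=7,
    )
    expr, ann, sigs = sk.generate_expression_fixture(cfg)
    return {"config": cfg, "expr": expr, "ann": ann, "signatures": sigs}


@pytest.fixture(scope="session")
def genomic_fixture():
    cfg = sk.GenomicSimConfig(seed=17)
    tf, partner, tss, stats, truth = sk.generate_genomic_fixture(cfg)
    return {"config": cfg, "tf": tf, "partner": partner, "tss": tss, "stats": stats, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
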