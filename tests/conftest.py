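import numpy as np
import pandas as pd
import pytest

from carballoc import exprkit, simdata


def small_config(seed: int = 11, **overrides) -> simdata.SimConfig:
    base = dict(
        seed=seed,
        n_genes=1000,
        n_modules=3,
        module_size_range=(60, 90),
        t6p_set_size=100,
        n_de_genes=80,
    )
    base.update(overrides)
    return simdata.SimConfig(**base)


@pytest.fixture(scope="session")
def bundle() -> simdata.SimBundle:
    """One small simulated dataset shared across tests."""
    return simdata.simulate_all(small_config())


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    paths = simdata.write_fixtures(str(outdir), bundle)
    return paths


@pytest.fixture(scope="session")
def log_expr(bundle) -> pd.DataFrame:
    genes = bundle.truth.genes
    lengths = pd.Series(
        (genes["end"] - genes["start"]).to_numpy(), index=genes["gene_id"]
    )
    return exprkit.log_rpkm(exprkit.rpkm(bundle.counts, lengths))


def two_group_counts(rng, n_genes, n_reps, mu, dispersion, fold=None):
    """NB counts for a two-timepoint, one-genotype design plus sample sheet."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n_genes,))
    mu_b = mu if fold is None else mu * np.asarray(fold)
    r = 1.0 / dispersion
    a = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_genes, n_reps))
    b = rng.negative_binomial(r, r / (r + mu_b[:, None]), size=(n_genes, n_reps))
    cols = [f"A_T1_r{i}" for i in range(n_reps)] + [
        f"A_T2_r{i}" for i in range(n_reps)
    ]
    counts = pd.DataFrame(
        np.hstack([a, b]), columns=cols,
        index=[f"g{i}" for i in range(n_genes)],
    )
    samples = pd.DataFrame(
        {
            "sample": cols,
            "genotype": "A",
            "timepoint": ["T1"] * n_reps + ["T2"] * n_reps,
            "replicate": list(range(n_reps)) * 2,
        }
    )
    return counts, samples
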