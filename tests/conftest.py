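import numpy as np
import pytest

import polyhaz as ph


def weibull_cohort(rng, n, betas=None, p=5, freq=0.3, shape=4.5, scale=116.0,
                   censor=(55.0, 90.0)):
    """Small proportional-hazards survival sample for solver tests."""
    X = rng.binomial(2, freq, size=(n, p)).astype(float)
    lp = np.zeros(n) if betas is None else X @ np.asarray(betas, dtype=float)
    lp = lp - lp.mean()
    T = scale * (-np.log(rng.uniform(size=n)) / np.exp(lp)) ** (1.0 / shape)
    C = rng.uniform(*censor, size=n)
    event = T <= C
    time = np.where(event, T, C)
    return X, time, event


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated population shared by read-only tests."""
    cfg = ph.SimulationConfig(n_subjects=4000, n_snps=40, n_causal=10,
                              ld_dup_pairs=3, seed=314)
    g, phen = ph.simulate_cohort(cfg)
    return cfg, g, phen


@pytest.fixture(scope="session")
def scored_reference(small_cohort):
    """Weights, scores and a young-control percentile reference."""
    cfg, g, phen = small_cohort
    betas = cfg.resolved_betas()
    scores = g.counts[:, : cfg.n_causal] @ betas
    ref = ph.build_percentile_reference(scores, phen, max_age=70)
    return scores, ref
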