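import numpy as np
import pytest

from prefcal import syngen, trainer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gen():
    """Desk-scale generator config for fast unit tests."""
    return syngen.GeneratorConfig(n_cases=400, embed_dim=8, seed=3)


@pytest.fixture
def small_set(small_gen):
    return syngen.generate_scenarios(small_gen)


@pytest.fixture
def tiny_run_cfg(small_gen):
    """A short policy run (tiny warmup) for loop-level tests."""
    return trainer.RunConfig(epochs=14, batch_size=64, warmup_epochs=10,
                             eval_window=4, seed=11, generator=small_gen)


def balanced_two_point_set(n=100, d=4, y_lo=0.1, y_hi=0.9):
    """Scenario set with an exactly balanced two-point outcome, for
    closed-form error checks."""
    z = np.tile([0, 1], n // 2)
    y = np.where(z == 1, y_hi, y_lo)
    rng = np.random.default_rng(0)
    split = np.array(["test"] * n)
    split[: n // 2] = "train"
    cfg = syngen.GeneratorConfig(n_cases=n, embed_dim=d, seed=0)
    return syngen.ScenarioSet(
        outcomes=y.astype(float), labels=z.astype(np.int64),
        comm_embed=rng.normal(size=(n, d)), phys_embed=rng.normal(size=(n, d)),
        split=split, provenance=cfg)
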