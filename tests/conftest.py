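import numpy as np
import pytest

from bmselect import BetaPrior, Dataset, Partition
from bmselect.priors import MomentSpec, PriorConfig
from bmselect.simulate import SimConfig, simulate_dataset

# Moderate hyperparameters used for oracle cross-checks: the prior draws
# have good overlap with data generated from the same prior, so the
# prior-sampling Monte-Carlo estimator keeps a usable effective sample
# size (the benchmark moments, with their tiny within-group variance,
# collapse it for mismatched partitions).
GENTLE_MOMENTS = MomentSpec(
    mean_of_gamma=50.0, var_of_gamma=50.0, mean_of_m=0.0, var_of_m=0.02
)
GENTLE_NOISE = MomentSpec(mean_of_gamma=5e3, var_of_gamma=5e3)


@pytest.fixture
def gentle_config() -> PriorConfig:
    return PriorConfig(GENTLE_MOMENTS, BetaPrior(1.0, 1.0), GENTLE_NOISE)


def make_instance(seed: int, noise: MomentSpec | None = None, *,
                  moments: MomentSpec = GENTLE_MOMENTS,
                  p_range=(1, 3), n_range=(4, 11)):
    """One small random cohort drawn from the generative protocol."""
    rng = np.random.default_rng(seed)
    p = int(rng.integers(*p_range))
    n = int(rng.integers(*n_range))
    cfg = SimConfig(
        n_proteins=p, n_individuals=n, n_reps=1,
        moments=moments, noise_moments=noise, seed=seed,
    )
    truth = Partition.from_bitmask(int(rng.integers(0, 2**p)), p)
    clean, noisy = simulate_dataset(truth, cfg, rng)
    return cfg, truth, clean, noisy


@pytest.fixture
def toy_dataset() -> Dataset:
    # values on the scale of the gentle prior (m ~ 0 +- 0.14, within-group
    # sd ~ 0.14) so prior-sampling Monte-Carlo keeps a healthy ESS
    x = np.array([[0.10, 0.25, -0.05, 0.30, -0.20, 0.05]])
    statuses = np.array(["P", "P", "P", "H", "H", "H"])
    return Dataset(x, statuses)
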