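import pytest

from microloop import FitConfig, SyntheticDesign, generate_observations, reference_truth


@pytest.fixture(scope="session")
def truth():
    return reference_truth()


@pytest.fixture(scope="session")
def noiseless_obs(truth):
    obs, traj = generate_observations(truth, SyntheticDesign(noise_cv=0.0, rng_seed=11))
    return obs, traj


def light_fit_config(free, bounds, seed=7, **overrides):
    """A reduced annealing schedule for test-scale fits."""
    kwargs = dict(
        free_parameters=free,
        bounds=bounds,
        restarts=1,
        n_temps=15,
        steps_per_temp=15,
        rng_seed=seed,
    )
    kwargs.update(overrides)
    return FitConfig(**kwargs)
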