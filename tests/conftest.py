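import numpy as np
import pytest

from kvgating import KineticRates, simulate_three_state, voltage_dependent_activation

# wild-type inactivation: tau = 4.8 s, steady state 30% of peak
WT_KAPPA = 0.7 / 4.8
WT_LAMBDA = 0.3 / 4.8


@pytest.fixture(scope="session")
def activation():
    return voltage_dependent_activation()


@pytest.fixture(scope="session")
def wt_rates(activation):
    alpha, beta = activation
    return KineticRates(alpha=alpha, beta=beta, kappa=WT_KAPPA, lambda_=WT_LAMBDA)


@pytest.fixture(scope="session")
def wt_trace(wt_rates):
    """Noiseless 10-s wild-type sweep at +80 mV."""
    return simulate_three_state(wt_rates, step_voltage=80.0, duration=10.0, dt=0.01)


def exp_decay_trace(i_max, ss, tau, duration=10.0, dt=0.01, step_voltage=80.0):
    """Build an ideal decaying trace directly from the closed form."""
    from kvgating import CurrentTrace

    t = np.arange(0.0, duration + dt / 2, dt)
    return CurrentTrace(
        time=t,
        current=(i_max - ss) * np.exp(-t / tau) + ss,
        step_voltage=step_voltage,
    )
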