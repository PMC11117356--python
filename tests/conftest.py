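import numpy as np
import pytest
from scipy.integrate import solve_ivp

from neoperem import (
    IndividualParameters,
    PopulationParameters,
    Regimen,
    load_final_model,
)


@pytest.fixture(scope="session")
def final_pop() -> PopulationParameters:
    return load_final_model()


@pytest.fixture(scope="session")
def typical_ind(final_pop) -> IndividualParameters:
    return IndividualParameters(cl=final_pop.clp, v=final_pop.vp)


def ode_concentration(ind: IndividualParameters, reg: Regimen, times) -> np.ndarray:
    """Independent numeric oracle for the one-compartment infusion model.

    Integrates dA/dt = rate(t) - ke*A segment by segment between infusion
    breakpoints (the rate function is piecewise constant) with tight
    tolerances, and returns A/V at the requested times.
    """
    times = np.asarray(times, dtype=float)
    breaks = {0.0}
    for ev in reg.events:
        breaks.add(ev.start)
        breaks.add(ev.start + ev.duration)
    breaks.update(times.tolist())
    knots = sorted(b for b in breaks if b <= times.max() + 1e-12)

    def rate_at(t: float) -> float:
        return sum(ev.rate for ev in reg.events if ev.start <= t < ev.start + ev.duration)

    ke = ind.ke
    out = {}
    amount = 0.0
    for a, b in zip(knots, knots[1:] + [None]):
        out[a] = amount
        if b is None:
            break
        r = rate_at(0.5 * (a + b))
        sol = solve_ivp(
            lambda t, y: [r - ke * y[0]], (a, b), [amount],
            rtol=1e-11, atol=1e-13, dense_output=False, method="DOP853",
        )
        amount = float(sol.y[0, -1])
    return np.array([out[t] / ind.v for t in times])
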