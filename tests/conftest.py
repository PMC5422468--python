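import numpy as np
import pytest

import doeopt as dp


@pytest.fixture(scope="session")
def pb16():
    """The bundled 16-run, 14-factor screening design with responses."""
    return dp.load_fixture("gsh_pb16")


@pytest.fixture(scope="session")
def bbd13():
    """The bundled 13-run Box-Behnken design with responses."""
    return dp.load_fixture("gsh_bbd13")


@pytest.fixture(scope="session")
def bbd13_fit(bbd13):
    return dp.fit_quadratic(bbd13, bbd13.responses)


@pytest.fixture(scope="session")
def bbd_factors():
    return dp.load_fixture("gsh_factors_bbd")


def grid_maximum(fit, lo=-1.5, hi=1.5, steps=(0.02, 0.002, 0.0002)):
    """Pure grid-search oracle for the maximum of a fitted quadratic.

    Coarse sweep over [lo, hi]^3 with progressively finer local sweeps
    around the running best point; entirely independent of the closed-form
    stationary-point solve.
    """
    def best_on(axes):
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        B = fit.quadratic_form
        vals = fit.beta0 + pts @ fit.linear + np.einsum("ni,ij,nj->n", pts, B, pts)
        i = int(np.argmax(vals))
        return pts[i], float(vals[i])

    axes = [np.arange(lo, hi + steps[0] / 2, steps[0]) for _ in range(fit.k)]
    x0, v0 = best_on(axes)
    for prev, step in zip(steps, steps[1:]):
        half = 1.5 * prev
        axes = [
            np.arange(max(lo, c - half), min(hi, c + half) + step / 2, step)
            for c in x0
        ]
        x0, v0 = best_on(axes)
    return x0, v0
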