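"""Shared fixtures and independent analytic oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import binom

import collapse_kinetics as ck


def one_frame_law(i: int, pa: float, pd: float, pc_i: float = 0.0,
                  n_max_sim: int = 12) -> dict[int, float]:
    """Exact one-frame transition law of the simulator for a size-i region.

    Derived independently from the model definition: optional concerted
    collapse, then Binomial(i, pd) detachments, then -- only if the region
    survived -- a single edge attachment with probability pa (blocked at the
    simulated size cap).  Returns {final size j: probability}.
    """
    law: dict[int, float] = {}
    stay = 1.0 - pc_i
    law[0] = pc_i + stay * binom.pmf(0, i, 1.0 - pd)
    for j in range(1, i + 2):
        p = 0.0
        # j survivors, no attachment (or attachment blocked at the cap)
        p_j = binom.pmf(j, i, 1.0 - pd) if j <= i else 0.0
        blocked = 1.0 if j >= n_max_sim else 1.0 - pa
        p += p_j * blocked
        # j-1 survivors (>= 1) plus one attachment
        if 1 <= j - 1 <= i and (j - 1) < n_max_sim:
            p += binom.pmf(j - 1, i, 1.0 - pd) * pa
        law[j] = stay * p
    total = sum(law.values())
    assert abs(total - 1.0) < 1e-12
    return law


@pytest.fixture(scope="session")
def noiseless_imaging() -> ck.ImagingParams:
    return ck.ImagingParams(unit_intensity_cv=0.0, background_offset=0.0,
                            noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def stationary_cluster_kymo(noiseless_imaging):
    """A single stationary 3-myosin cluster rendered without noise."""
    params = ck.SimulationParams(pa=0.0, pd=0.0, p_nuc=0.0, n_frames=12,
                                 initial_regions=((64.0, 3),), seed=0)
    trace = ck.simulate_cluster_dynamics(params)
    kymo = ck.render_kymograph(trace, noiseless_imaging)
    return kymo, trace, noiseless_imaging
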