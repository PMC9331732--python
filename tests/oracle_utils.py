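"""Independent numerical oracles used only by the tests.

The trace oracle integrates the gating ODEs with an adaptive Runge-Kutta
solver instead of the simulator's per-segment closed forms; agreement
between the two is evidence that the closed-form synthesis is correct.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from kvclamp.gating import ChannelSpecies, inactivation_steady_state, inactivation_tau
from kvclamp.protocols import Sweep


def ode_current(species: ChannelSpecies, sweep: Sweep, thin: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Current under a sweep by direct ODE integration of the three gates.

    Returns (sample_indices, current) on every ``thin``-th sample of the
    simulator grid.  Tolerances are far tighter than the 1e-6 comparison
    level so the oracle's own error is negligible.
    """
    bounds = sweep.segment_sample_bounds()
    dt_ms = 1e3 / sweep.sampling_rate
    hold = sweep.holding
    y = np.array(
        [
            species.m_inf(hold),
            inactivation_steady_state(hold, species.activation),
            inactivation_steady_state(hold, species.activation),
        ]
    )
    idx_all, cur_all = [], []
    for seg, (i0, i1) in zip(sweep.segments, bounds):
        V = seg.level
        m_inf = species.m_inf(V)
        tau_m = float(species.tau_m(V))
        h_inf = inactivation_steady_state(V, species.activation)
        tau_hf = 1e3 * inactivation_tau(V, species.inact.tau_fast, species.inact.tau_recovery)
        tau_hs = 1e3 * inactivation_tau(V, species.inact.tau_slow, species.inact.tau_recovery)

        def rhs(t, y):
            m, hf, hs = y
            return [(m_inf - m) / tau_m, (h_inf - hf) / tau_hf, (h_inf - hs) / tau_hs]

        local_idx = np.arange(0, i1 - i0, thin)
        t_eval = local_idx * dt_ms
        sol = solve_ivp(
            rhs,
            (0.0, seg.duration),
            y,
            t_eval=t_eval,
            rtol=1e-11,
            atol=1e-13,
            method="DOP853",
        )
        m, hf, hs = sol.y
        ff = species.inact.frac_fast
        O = m * (ff * hf + (1 - ff) * hs)
        idx_all.append(local_idx + i0)
        cur_all.append(species.g_max * O * (V - species.E_rev))
        end = solve_ivp(rhs, (0.0, seg.duration), y, rtol=1e-11, atol=1e-13, method="DOP853")
        y = end.y[:, -1]
    return np.concatenate(idx_all), np.concatenate(cur_all)
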