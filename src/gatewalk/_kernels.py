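"""Compiled stepping kernels for the two gating random-walk engines.

Both kernels consume a single pre-drawn array of uniforms in a fixed order
(one draw per reaction-coordinate step, one extra draw whenever the slow
process is due), so a run is fully determined by the uniform stream.  A pure
Python mirror of each kernel lives in the test suite and is checked for
bit-identical output.

Conventions shared by both kernels:

* lattice nodes are the integers in ``[b1, b2]`` with the threshold node TP
  itself excluded; a jump TP-1 -> TP+1 (or back) crosses the barrier peak,
* the crossing draw uses the uphill half-step into the barrier,
  ``dU = U(TP) - U(TP -/+ 1/2) = u_barrier / 3``,
* a move past a reflecting limit is rejected (the walker stays put),
* ``period <= 0`` freezes the slow process (negative-control runs).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sim_model1(n_steps, b_max, b_init, tp, u_barrier, f_d, period,
               rc0, u, record, rc_out, b_out):
    """Fluctuating-boundary walk. Returns int8 state array (1 = open)."""
    states = np.empty(n_steps, dtype=np.int8)
    b2 = b_init
    rc = rc0
    # barrier slope is u_barrier / 1.5 kT per rcu; the crossing decision
    # uses the half-step into the peak
    p_cross = 0.5 - (u_barrier / 3.0) / 4.0
    if p_cross < 0.0:
        p_cross = 0.0
    p_flat = 0.5 - f_d / 4.0
    if p_flat < 0.0:
        p_flat = 0.0
    elif p_flat > 1.0:
        p_flat = 1.0
    ui = 0
    for i in range(1, n_steps + 1):
        r = u[ui]
        ui += 1
        if rc == tp - 1:
            if r < p_cross:
                rc = tp + 1
            elif rc - 1 >= -b2:
                rc -= 1
        elif rc == tp + 1:
            if r < p_cross:
                rc = tp - 1
            elif rc + 1 <= b2:
                rc += 1
        else:
            if r < p_flat:
                if rc + 1 <= b2 and rc + 1 != tp:
                    rc += 1
            else:
                if rc - 1 >= -b2 and rc - 1 != tp:
                    rc -= 1
        if period > 0 and i % period == 0:
            r2 = u[ui]
            ui += 1
            if r2 < 0.5:  # expand both half-spaces
                if b2 + 1 <= b_max:
                    b2 += 1
            else:  # shrink both half-spaces
                if b2 - 1 >= 2:
                    b2 -= 1
                    if rc > b2:
                        rc = b2
                    elif rc < -b2:
                        rc = -b2
        states[i - 1] = 1 if rc > tp else 0
        if record:
            rc_out[i - 1] = rc
            b_out[i - 1] = b2
    return states


@njit(cache=True)
def sim_model2(n_steps, b1, b2, tp, u_barrier, k0, dk, kmax, period,
               rc0, u, record, rc_out, k_out):
    """Fluctuating-drift walk on fixed boundaries.

    The drift slope is tracked as an integer multiple ``k`` of the increment
    ``dk`` so that reflection at ``+/- kmax * dk`` is exact.
    """
    states = np.empty(n_steps, dtype=np.int8)
    rc = rc0
    k = k0
    p_cross = 0.5 - (u_barrier / 3.0) / 4.0
    if p_cross < 0.0:
        p_cross = 0.0
    ui = 0
    for i in range(1, n_steps + 1):
        r = u[ui]
        ui += 1
        if rc == tp - 1:
            if r < p_cross:
                rc = tp + 1
            elif rc - 1 >= b1:
                rc -= 1
        elif rc == tp + 1:
            if r < p_cross:
                rc = tp - 1
            elif rc + 1 <= b2:
                rc += 1
        else:
            # outer slopes are antisymmetric about TP: +A left, -A right
            du = k * dk if rc < tp else -k * dk
            p = 0.5 - du / 4.0
            if p < 0.0:
                p = 0.0
            elif p > 1.0:
                p = 1.0
            if r < p:
                if rc + 1 <= b2 and rc + 1 != tp:
                    rc += 1
            else:
                if rc - 1 >= b1 and rc - 1 != tp:
                    rc -= 1
        if period > 0 and i % period == 0:
            r2 = u[ui]
            ui += 1
            if r2 < 0.5:
                if k + 1 <= kmax:
                    k += 1
            else:
                if k - 1 >= -kmax:
                    k -= 1
        states[i - 1] = 1 if rc > tp else 0
        if record:
            rc_out[i - 1] = rc
            k_out[i - 1] = k
    return states
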