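"""Independent oracles for the walk engines.

``walk_reference`` is a deliberately plain Python re-implementation of the
stepping rules, consuming the same uniform stream as the compiled kernels;
``stationary_distribution`` and ``expected_mean_dwell`` solve the frozen
(slow-process-off) walk exactly as a finite Markov chain.
"""

import numpy as np


def walk_reference(cfg, n_steps, u):
    """Pure-Python mirror of the stepping kernels (frozen or not)."""
    tp = cfg.tp
    p_cross = 0.5 - (cfg.u_barrier / 3.0) / 4.0
    st = cfg.initial_state()
    rc, b1, b2 = st.rc, st.b1, st.b2
    k, kmax = 0, (round(cfg.drift_max / cfg.drift_step)
                  if cfg.model_id == 2 else 0)
    period = cfg.period
    states = np.empty(n_steps, dtype=np.int8)
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
            if cfg.model_id == 1:
                du = cfg.f_d
            else:
                du = k * cfg.drift_step if rc < tp else -k * cfg.drift_step
            p = min(max(0.5 - du / 4.0, 0.0), 1.0)
            if r < p:
                if rc + 1 <= b2 and rc + 1 != tp:
                    rc += 1
            else:
                if rc - 1 >= b1 and rc - 1 != tp:
                    rc -= 1
        if period > 0 and i % period == 0:
            r2 = u[ui]
            ui += 1
            if cfg.model_id == 1:
                if r2 < 0.5:
                    if b2 + 1 <= cfg.b_max:
                        b2 += 1
                        b1 = -b2
                else:
                    if b2 - 1 >= 2:
                        b2 -= 1
                        b1 = -b2
                        rc = min(max(rc, b1), b2)
            else:
                if r2 < 0.5:
                    if k + 1 <= kmax:
                        k += 1
                else:
                    if k - 1 >= -kmax:
                        k -= 1
        states[i - 1] = 1 if rc > tp else 0
    return states


def _nodes(cfg):
    st = cfg.initial_state()
    return [x for x in range(st.b1, st.b2 + 1) if x != cfg.tp]


def transition_matrix(cfg):
    """Exact one-step transition matrix of the frozen walk."""
    assert cfg.period == 0, "oracle applies to the frozen slow process"
    nodes = _nodes(cfg)
    idx = {x: i for i, x in enumerate(nodes)}
    tp = cfg.tp
    p_cross = 0.5 - (cfg.u_barrier / 3.0) / 4.0
    st = cfg.initial_state()
    n = len(nodes)
    P = np.zeros((n, n))
    for x in nodes:
        i = idx[x]
        if x == tp - 1:
            P[i, idx[tp + 1]] += p_cross
            if x - 1 >= st.b1:
                P[i, idx[x - 1]] += 1 - p_cross
            else:
                P[i, i] += 1 - p_cross
        elif x == tp + 1:
            P[i, idx[tp - 1]] += p_cross
            if x + 1 <= st.b2:
                P[i, idx[x + 1]] += 1 - p_cross
            else:
                P[i, i] += 1 - p_cross
        else:
            if cfg.model_id == 1:
                du = cfg.f_d
            else:
                du = 0.0 if cfg.model_id == 2 else None
            p = min(max(0.5 - du / 4.0, 0.0), 1.0)
            if x + 1 <= st.b2 and x + 1 != tp:
                P[i, idx[x + 1]] += p
            else:
                P[i, i] += p
            if x - 1 >= st.b1 and x - 1 != tp:
                P[i, idx[x - 1]] += 1 - p
            else:
                P[i, i] += 1 - p
    return nodes, P


def stationary_distribution(cfg):
    nodes, P = transition_matrix(cfg)
    w, v = np.linalg.eig(P.T)
    i = np.argmin(np.abs(w - 1))
    pi = np.real(v[:, i])
    pi = pi / pi.sum()
    return nodes, pi


def expected_mean_dwell(cfg, state):
    """Exact mean dwell (steps) of one state for the frozen walk.

    Renewal argument: dwells in a state alternate with crossings, so the
    mean dwell equals the stationary occupancy of that state divided by
    the per-step crossing flux out of it, pi(TP -/+ 1) * p_cross.
    """
    nodes, pi = stationary_distribution(cfg)
    idx = {x: i for i, x in enumerate(nodes)}
    p_cross = 0.5 - (cfg.u_barrier / 3.0) / 4.0
    tp = cfg.tp
    if state == 1:
        occ = sum(pi[idx[x]] for x in nodes if x > tp)
        flux = pi[idx[tp + 1]] * p_cross
    else:
        occ = sum(pi[idx[x]] for x in nodes if x < tp)
        flux = pi[idx[tp - 1]] * p_cross
    return occ / flux
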