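"""Independent small-scale oracles used by the test suite.

These are deliberately separate from the simulation engine: they compute
reference values by direct linear algebra on a discretised state space, not
by stochastic simulation.
"""

from __future__ import annotations

import numpy as np

from twindom.kinetics import sigmoid_rate


def stationary_sigma_master_equation(cfg, lk_half_range: int = 160) -> float:
    """Stationary mean supercoiling density of the transcription-free domain.

    Without transcription the domain is a single segment whose linking
    number performs a continuous-time Markov jump process on an integer
    lattice: +1 per TopoI event (rate = TopoI law at sigma times the total
    flank length) and -2 per gyrase cycle, where a gyrase binding performs
    a geometric number of cycles (mean rho_G) truncated as soon as sigma
    reaches the binding threshold sigma_rho.  The stationary distribution
    is obtained by solving pi Q = 0 directly.
    """
    h = cfg.h
    total = cfg.total_length
    Lk0 = total / h
    base = (1.0 + cfg.sigma_start) * Lk0
    lks = base + np.arange(-lk_half_range, lk_half_range + 1, dtype=float)
    n = len(lks)
    binding_length = cfg.D_up + cfg.D_down
    p = 1.0 / cfg.rho_G

    Q = np.zeros((n, n))
    for i, lk in enumerate(lks):
        sigma = (lk - Lk0) / Lk0
        rate_T = sigmoid_rate(cfg.topoI, sigma) * binding_length
        if i + 1 < n:
            Q[i, i + 1] += rate_T
        if sigma > cfg.sigma_rho:
            rate_G = sigmoid_rate(cfg.gyrase, sigma) * binding_length
            # number of cycles that fit before sigma reaches sigma_rho
            m_max = 0
            lk_cur = lk
            while (lk_cur - Lk0) / Lk0 > cfg.sigma_rho and m_max < n:
                m_max += 1
                lk_cur -= 2.0
            for m in range(1, m_max + 1):
                prob = p * (1.0 - p) ** (m - 1) if m < m_max else (1.0 - p) ** (m - 1)
                j = max(i - 2 * m, 0)
                Q[i, j] += rate_G * prob
        Q[i, i] -= Q[i].sum()

    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    sigmas = (lks - Lk0) / Lk0
    return float(np.dot(pi, sigmas))
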