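"""Compiled inner loop for whole-population bandit play.

All randomness is drawn outside the kernel (per-agent uniforms for choices,
standard normals for payoffs) so that batch execution is bit-identical to
per-agent sequential runs given the same sub-streams.
"""

import numpy as np
from numba import njit

# Softmax exponent clip: beyond +/-EXP_CLIP the choice probability saturates
# at machine 0/1 instead of overflowing.
EXP_CLIP = 700.0


@njit(cache=False)
def play_population(alpha_p, alpha_n, beta, mu, sigma, uniforms, z, n_trials, window):
    """Run every agent through K tasks of ``n_trials`` trials each.

    Parameters: gene arrays of shape (N,); ``mu``/``sigma`` of shape (K, 2)
    in option order [risky, safe]; ``uniforms``/``z`` of shape
    (N, K * n_trials), consumed left to right, one uniform and one normal per
    trial.  Values start at zero in every task; the unchosen option is never
    updated; a zero prediction error takes the positive-rate branch.

    Returns (safe_counts[N, K], safe_counts_window[N, K], payoff_sum[N]):
    safe-option choice counts over all trials and over the last ``window``
    trials of each task, and each agent's total payoff across everything.
    """
    n_agents = alpha_p.shape[0]
    n_tasks = mu.shape[0]
    safe_counts = np.zeros((n_agents, n_tasks), np.int64)
    safe_window = np.zeros((n_agents, n_tasks), np.int64)
    payoff_sum = np.zeros(n_agents)
    for i in range(n_agents):
        col = 0
        for k in range(n_tasks):
            v_risky = 0.0
            v_safe = 0.0
            for t in range(n_trials):
                x = beta[i] * (v_risky - v_safe)
                if x > EXP_CLIP:
                    p_risky = 1.0
                elif x < -EXP_CLIP:
                    p_risky = 0.0
                else:
                    p_risky = 1.0 / (1.0 + np.exp(-x))
                if uniforms[i, col] < p_risky:
                    reward = mu[k, 0] + sigma[k, 0] * z[i, col]
                    delta = reward - v_risky
                    if delta >= 0.0:
                        v_risky += alpha_p[i] * delta
                    else:
                        v_risky += alpha_n[i] * delta
                else:
                    reward = mu[k, 1] + sigma[k, 1] * z[i, col]
                    delta = reward - v_safe
                    if delta >= 0.0:
                        v_safe += alpha_p[i] * delta
                    else:
                        v_safe += alpha_n[i] * delta
                    safe_counts[i, k] += 1
                    if t >= n_trials - window:
                        safe_window[i, k] += 1
                payoff_sum[i] += reward
                col += 1
    return safe_counts, safe_window, payoff_sum
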