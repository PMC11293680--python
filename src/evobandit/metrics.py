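"""Summary statistics on behavior and genes.

Behavioral statistics are fractions of safe-option choices ("risk-aversion
rates"), computed over all trials for evolutionary summaries and over the
last 100 trials for the equal-EV assay.  Gene statistics follow the field's
conventions: the Niv index ``(alpha_n - alpha_p) / (alpha_n + alpha_p)``
summarises learning-rate asymmetry per agent, Cohen's d with the pooled SD
``sqrt((SD_p^2 + SD_n^2) / 2)`` compares the two rates across a population,
and the SD ratio ``SD_p / SD_n`` compares their spread.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .agents import BehaviorRecord
from .tasks import SAFE

__all__ = [
    "risk_aversion_rate",
    "niv_index",
    "cohens_d",
    "sd_ratio",
    "gain_loss_difference",
    "pearson_correlation",
]


def risk_aversion_rate(record: BehaviorRecord, window: int | str = "all") -> float:
    """Fraction of safe-option choices within a trial window.

    ``window="all"`` uses every trial; an integer ``k`` uses only the last
    ``k`` trials (e.g. 100 of 500 for the assay, excluding not-yet-learned
    early behavior).  Depends on choices only, never on reward values.
    """
    choices = record.choices
    if window == "all":
        selected = choices
    else:
        k = int(window)
        if k < 1 or k > choices.size:
            raise ValueError(
                f"window must be between 1 and the trial count, got {window}"
            )
        selected = choices[-k:]
    return float(np.mean(selected == SAFE))


def niv_index(alpha_p, alpha_n):
    """Learning-rate asymmetry ``(alpha_n - alpha_p) / (alpha_n + alpha_p)``.

    Lies in [-1, 1]; positive values indicate dominance of negative-error
    learning.  Undefined when both rates are zero — that raises rather than
    silently returning 0.  Accepts scalars or arrays.
    """
    alpha_p = np.asarray(alpha_p, dtype=float)
    alpha_n = np.asarray(alpha_n, dtype=float)
    total = alpha_p + alpha_n
    if np.any(total <= 0):
        raise ValueError("Niv index is undefined when alpha_p + alpha_n == 0")
    out = (alpha_n - alpha_p) / total
    return float(out) if out.ndim == 0 else out


def cohens_d(alpha_p_values, alpha_n_values) -> float:
    """Effect size between the two learning rates of a population.

    ``d = (M_p - M_n) / sqrt((SD_p^2 + SD_n^2) / 2)`` with sample SDs; a
    positive d means the mean positive learning rate exceeds the negative
    one.
    """
    a_p = np.asarray(alpha_p_values, dtype=float)
    a_n = np.asarray(alpha_n_values, dtype=float)
    pooled = np.sqrt((a_p.std(ddof=1) ** 2 + a_n.std(ddof=1) ** 2) / 2.0)
    if pooled == 0:
        raise ValueError("pooled SD is zero; Cohen's d is undefined")
    return float((a_p.mean() - a_n.mean()) / pooled)


def sd_ratio(alpha_p_values, alpha_n_values) -> float:
    """Ratio of the SD of evolved ``alpha_p`` to that of evolved ``alpha_n``."""
    sd_n = np.asarray(alpha_n_values, dtype=float).std(ddof=1)
    if sd_n == 0:
        raise ValueError("SD of alpha_n is zero; ratio is undefined")
    sd_p = np.asarray(alpha_p_values, dtype=float).std(ddof=1)
    return float(sd_p / sd_n)


def gain_loss_difference(gain_rates, loss_rates) -> float:
    """Mean risk aversion in gain-domain tasks minus that in loss-domain tasks.

    Positive values mean the agent was more risk averse in the gain domain —
    the prospect-theory direction.
    """
    gain = np.asarray(gain_rates, dtype=float)
    loss = np.asarray(loss_rates, dtype=float)
    if gain.size == 0 or loss.size == 0:
        raise ValueError("rates for both domains are required")
    return float(gain.mean() - loss.mean())


def pearson_correlation(x, y) -> float:
    """Product-moment correlation between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation is undefined for a degenerate sample")
    return float(stats.pearsonr(x, y).statistic)
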