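"""Duo-trio sensory panel statistics.

In a duo-trio test each panelist sniffs a reference and picks which of
two samples matches it; under the null (no perceivable difference) each
pick is a fair coin, so the number of correct picks is Binomial(n, 0.5).
Small panels call for the exact one-proportion binomial test,
right-tailed: p = P(X >= k).  The z statistic (no continuity correction)
is reported alongside for comparison with normal-approximation tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt

from scipy.special import gammaln, logsumexp
import numpy as np

_EXACT_N_MAX = 64


@dataclass
class DuoTrioResult:
    n_panelists: int
    n_correct: int
    null_prob: float
    z: float
    p_value: float
    alpha: float
    reject: bool

    def verdict(self) -> str:
        rel = "<" if self.p_value < self.alpha else ">="
        action = "reject" if self.reject else "do not reject"
        return (
            f"{self.n_correct}/{self.n_panelists} correct, z = {self.z:.2f}, "
            f"exact right-tailed p = {self.p_value:.7g} {rel} alpha = "
            f"{self.alpha:g}: {action} the null of no perceivable difference"
        )


def _validate(k: int, n: int, p0: float) -> None:
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError(f"null probability must be in (0, 1), got {p0}")


def binomial_right_tail(k: int, n: int, p0: float = 0.5) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p0).

    Integer binomial coefficients for n <= 64; log-sum-exp otherwise.
    """
    _validate(k, n, p0)
    if k == 0:
        return 1.0
    if n <= _EXACT_N_MAX:
        return float(
            sum(comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1))
        )
    i = np.arange(k, n + 1)
    logs = (
        gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        + i * np.log(p0) + (n - i) * np.log1p(-p0)
    )
    return float(min(1.0, np.exp(logsumexp(logs))))


def z_statistic(k: int, n: int, p0: float = 0.5) -> float:
    """(k - n p0) / sqrt(n p0 (1 - p0)), no continuity correction."""
    _validate(k, n, p0)
    var = n * p0 * (1 - p0)
    if var <= 0:
        raise ValueError("degenerate variance")
    return (k - n * p0) / sqrt(var)


def duo_trio_report(
    k: int, n: int, p0: float = 0.5, alpha: float = 0.05
) -> DuoTrioResult:
    """Assemble the exact test, z statistic and reject/not-reject verdict."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = binomial_right_tail(k, n, p0)
    return DuoTrioResult(
        n_panelists=int(n),
        n_correct=int(k),
        null_prob=float(p0),
        z=z_statistic(k, n, p0),
        p_value=p,
        alpha=float(alpha),
        reject=p < alpha,
    )
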