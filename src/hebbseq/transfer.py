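"""Current-to-rate transfer functions.

Three families of static f-I curves map a population's synaptic current
``u`` to its average firing rate ``r = phi(u)``:

``SigmoidTF``
    Smooth saturating sigmoid, ``phi(u) = (1 + tanh(a (u + b))) / 2``.
    Rates are normalized to (0, 1).
``PiecewiseLinearTF``
    Threshold-linear with hard saturation; the workhorse for analytic
    bifurcation boundaries since the network dynamics become piecewise
    linear.
``PiecewiseNonlinearTF``
    Supralinear (quadratic) onset crossing over to a square-root branch,
    the canonical shape for neurons near a saddle-node bifurcation to
    periodic firing.  Unbounded for large currents.

All families are monotone non-decreasing, non-negative, and vectorized
over NumPy arrays.  Default parameters normalize the maximum rate to 1
(piecewise linear: slope 1, threshold 0, saturation 1), so rates read as
fractions of the maximum rate and relative activity thresholds are
well-defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SigmoidTF",
    "PiecewiseLinearTF",
    "PiecewiseNonlinearTF",
    "TransferFunction",
    "evaluate",
    "max_rate",
    "normalizer",
    "from_config",
]


@dataclass(frozen=True)
class SigmoidTF:
    """Sigmoidal transfer function ``phi(u) = (1 + tanh(a (u + b))) / 2``.

    Parameters
    ----------
    a : gain (1 / current units), must be positive.
    b : offset (current units); ``phi(-b) = 1/2``.
    """

    a: float = 4.0
    b: float = -0.5

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"sigmoid gain a must be positive, got {self.a}")

    def __call__(self, u):
        return 0.5 * (1.0 + np.tanh(self.a * (np.asarray(u, dtype=float) + self.b)))

    @property
    def max_rate(self) -> float:
        return 1.0

    @property
    def bounded(self) -> bool:
        return True

    def reference_current(self) -> float:
        """Current at which the rate reaches 95% of the maximum."""
        return -self.b + math.atanh(0.9) / self.a


@dataclass(frozen=True)
class PiecewiseLinearTF:
    """Threshold-linear transfer function with saturation.

    ``phi(u) = 0`` for ``u < theta``, ``nu (u - theta)`` on
    ``[theta, u_c]`` and ``nu (u_c - theta)`` above.
    """

    nu: float = 1.0
    theta: float = 0.0
    u_c: float = 1.0

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError(f"slope nu must be positive, got {self.nu}")
        if not self.theta < self.u_c:
            raise ValueError(
                f"threshold theta ({self.theta}) must be below saturation u_c ({self.u_c})"
            )

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        return self.nu * np.clip(u - self.theta, 0.0, self.u_c - self.theta)

    @property
    def max_rate(self) -> float:
        return self.nu * (self.u_c - self.theta)

    @property
    def bounded(self) -> bool:
        return True

    def reference_current(self) -> float:
        return self.u_c


@dataclass(frozen=True)
class PiecewiseNonlinearTF:
    """Supralinear onset with a square-root branch at high currents.

    With ``x = (u - theta_t) / (u_ct - theta_t)``:
    ``phi = 0`` for ``x < 0``, ``nu_t x**2`` on ``[0, 1]`` and
    ``2 nu_t sqrt(x - 3/4)`` above.  Both branches equal ``nu_t`` at the
    crossover ``u = u_ct``; the function is continuous and unbounded.
    """

    nu_t: float = 1.0
    theta_t: float = 0.0
    u_ct: float = 1.0

    def __post_init__(self) -> None:
        if not self.nu_t > 0:
            raise ValueError(f"rate scale nu_t must be positive, got {self.nu_t}")
        if not self.theta_t < self.u_ct:
            raise ValueError(
                f"threshold theta_t ({self.theta_t}) must be below crossover "
                f"u_ct ({self.u_ct})"
            )

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        x = (u - self.theta_t) / (self.u_ct - self.theta_t)
        quad = self.nu_t * np.square(np.clip(x, 0.0, None))
        sqrt = 2.0 * self.nu_t * np.sqrt(np.clip(x - 0.75, 0.0, None))
        return np.where(x <= 1.0, quad, sqrt)

    @property
    def max_rate(self) -> float:
        return math.inf

    @property
    def bounded(self) -> bool:
        return False

    def reference_current(self) -> float:
        """Reference on the square-root branch used to normalize relative thresholds."""
        return 2.0 * self.u_ct


TransferFunction = SigmoidTF | PiecewiseLinearTF | PiecewiseNonlinearTF


def evaluate(tf: TransferFunction, u):
    """Evaluate ``phi(u)`` elementwise (functional form of ``tf(u)``)."""
    return tf(u)


def max_rate(tf: TransferFunction) -> float:
    """Supremum of the transfer function; ``inf`` flags an unbounded family."""
    return tf.max_rate


def normalizer(tf: TransferFunction) -> float:
    """Finite rate scale used by relative activity thresholds.

    The maximum rate for bounded families; for the unbounded piecewise
    non-linear family, the rate at the configured reference current.
    """
    m = tf.max_rate
    if math.isfinite(m):
        return m
    return float(tf(tf.reference_current()))


_FAMILIES = {
    "sigmoid": (SigmoidTF, ("a", "b")),
    "pl": (PiecewiseLinearTF, ("nu", "theta", "u_c")),
    "pnl": (PiecewiseNonlinearTF, ("nu_t", "theta_t", "u_ct")),
}


def from_config(family: str, **params) -> TransferFunction:
    """Build a transfer function from a config family tag and parameters."""
    try:
        cls, fields = _FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown transfer family {family!r}; expected one of {sorted(_FAMILIES)}"
        ) from None
    unknown = set(params) - set(fields)
    if unknown:
        raise ValueError(f"unknown parameters for {family!r}: {sorted(unknown)}")
    return cls(**params)
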