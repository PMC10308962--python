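"""Incomplete-metastable-equilibrium simulation.

Real communities are not at metastable equilibrium; chemical adaptation is
the hypothesis of an *incomplete* equilibrium.  The simulation mixes an
equilibrium Z_C-vs-Eh7 step profile (from the stability model) with the
Z_C of randomly drawn taxa chosen to show essentially zero trend, using a
default weight of 20% equilibrium / 80% random.  Because OLS slopes are
linear in the response, the mixture slope is exactly

    m_mix = w_eq * m_eq + (1 - w_eq) * m_rand,

so a zero-slope random pool and an equilibrium profile with slope
0.665 1/V give a mixture slope of 0.133 1/V at w_eq = 0.2.  Adding the
random component both shrinks the slope and widens its confidence
interval, which is what makes the signal detectable but noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import RegressionFit, ols_fit
from .thermo import StepProfile

__all__ = [
    "EquilibriumMix",
    "sample_equilibrium_profile",
    "select_near_zero_pool",
    "mix_and_fit",
]

#: "Close to zero" slope tolerance for the random pool, in 1/V; an order of
#: magnitude below the smallest global slope of interest (~0.016/V).
DEFAULT_SLOPE_TOLERANCE = 0.005


@dataclass
class EquilibriumMix:
    """Aligned Eh7 (V), equilibrium Z_C and random-taxon Z_C series, with
    the equilibrium weight ``w_eq`` (default 0.20)."""

    eh7_V: np.ndarray
    zc_eq: np.ndarray
    zc_rand: np.ndarray
    w_eq: float = 0.20
    seed: int | None = None

    def __post_init__(self) -> None:
        self.eh7_V = np.asarray(self.eh7_V, dtype=float)
        self.zc_eq = np.asarray(self.zc_eq, dtype=float)
        self.zc_rand = np.asarray(self.zc_rand, dtype=float)
        n = len(self.eh7_V)
        if n < 3 or len(self.zc_eq) != n or len(self.zc_rand) != n:
            raise ValueError("series must share a common length >= 3")
        if not 0.0 <= self.w_eq <= 1.0:
            raise ValueError("w_eq must be in [0, 1]")

    @property
    def zc_mix(self) -> np.ndarray:
        return self.w_eq * self.zc_eq + (1.0 - self.w_eq) * self.zc_rand


def sample_equilibrium_profile(
    profile: StepProfile, n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Read the equilibrium step profile at equally spaced Eh7 values.

    Returns (eh7_V, zc_eq); the Eh grid spans the profile domain with both
    endpoints included.  Eh equals Eh7 for a pH-7 profile.
    """
    if n_points < 3:
        raise ValueError("need at least 3 sampling points")
    if profile.n_segments < 1:
        raise ValueError("empty profile")
    lo, hi = profile.domain
    eh_mV = np.linspace(lo, hi, n_points)
    return eh_mV / 1000.0, profile.lookup(eh_mV)


def select_near_zero_pool(
    taxa_zc: np.ndarray,
    eh7_V: np.ndarray,
    tolerance: float = DEFAULT_SLOPE_TOLERANCE,
    seed: int = 0,
    max_draws: int = 10000,
) -> tuple[np.ndarray, int]:
    """Draw random taxa until their Z_C shows |OLS slope| < tolerance.

    Each draw assigns ``len(eh7_V)`` pool members (without replacement) to
    the Eh7 points.  Deterministic under ``seed``.  Returns the accepted
    Z_C assignment and the number of draws used.
    """
    taxa_zc = np.asarray(taxa_zc, dtype=float)
    eh7_V = np.asarray(eh7_V, dtype=float)
    n = len(eh7_V)
    if len(taxa_zc) < n:
        raise ValueError("taxon pool smaller than the number of Eh7 points")
    rng = np.random.default_rng(seed)
    for draw in range(1, max_draws + 1):
        zc = rng.choice(taxa_zc, size=n, replace=False)
        if np.ptp(zc) == 0:
            return zc, draw          # constant pool: slope exactly 0
        if abs(ols_fit(eh7_V, zc).m) < tolerance:
            return zc, draw
    raise RuntimeError(
        f"no assignment with |slope| < {tolerance} in {max_draws} draws; "
        f"consider a larger tolerance"
    )


def mix_and_fit(mix: EquilibriumMix) -> RegressionFit:
    """OLS fit of the mixed Z_C series against Eh7.

    By linearity of least squares the slope equals
    ``w_eq * slope(zc_eq) + (1 - w_eq) * slope(zc_rand)`` exactly.
    """
    return ols_fit(mix.eh7_V, mix.zc_mix, dataset="equilibrium-mix")
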