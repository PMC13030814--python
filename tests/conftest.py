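"""Shared fixtures and independent oracles.

The Gaussian-deficit pit T(x) = rim - amp * exp(-x^2 / (2 sigma^2)) has a
closed-form derivative, so every morphometry quantity has an analytic or
numeric-quadrature oracle independent of the implementation under test:

* the outer derivative-threshold crossing at fraction f solves
  u * exp(-u^2/2) = f * exp(-1/2) for u > 1 (edge at x = u * sigma);
* pit depth at that threshold is amp * (1 - exp(-u^2/2)) (the chord is
  nearly flat at the rim level for symmetric pits);
* CFT is rim - amp * sigma * sqrt(pi/2) * erf(500 / (sigma sqrt 2)) / 500;
* the pointwise mean slope is the quadrature mean of
  arctan(amp * x / sigma^2 * exp(-x^2 / (2 sigma^2))) over the wall.
"""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import erf

from foveage import synth_ilm_profile


def outer_crossing_u(fraction: float) -> float:
    """Outer root of u * exp(-u^2/2) = fraction * exp(-1/2)."""
    return brentq(lambda u: u * np.exp(-u * u / 2)
                  - fraction * np.exp(-0.5), 1.0, 8.0, xtol=1e-12)


def oracle_edges(sigma: float, fraction: float = 0.5) -> float:
    """Edge position (µm) on each side of a Gaussian pit."""
    return outer_crossing_u(fraction) * sigma


def oracle_depth(amp: float, fraction: float = 0.5) -> float:
    u = outer_crossing_u(fraction)
    return amp * (1.0 - np.exp(-u * u / 2))


def oracle_diameter(sigma: float, fraction: float = 0.5) -> float:
    return 2.0 * oracle_edges(sigma, fraction)


def oracle_cft(rim: float, amp: float, sigma: float) -> float:
    return rim - amp * (sigma * np.sqrt(np.pi / 2)
                        * erf(500.0 / (sigma * np.sqrt(2))) / 500.0)


def oracle_max_slope(amp: float, sigma: float) -> float:
    """max |T'| = amp * exp(-1/2) / sigma, attained at x = sigma."""
    return amp * np.exp(-0.5) / sigma


def oracle_mean_slope(amp: float, sigma: float,
                      fraction: float = 0.5) -> float:
    """Quadrature mean of arctan|T'| (degrees) over one wall (0, edge)."""
    edge = oracle_edges(sigma, fraction)

    def ang(x):
        return np.degrees(np.arctan(amp * x / sigma**2
                                    * np.exp(-x * x / (2 * sigma**2))))
    val, _ = quad(ang, 0.0, edge, limit=200)
    return val / edge


@pytest.fixture
def gaussian_pit():
    """Factory for (optionally noisy) Gaussian-deficit ILM profiles."""
    def make(rim=280.0, amp=120.0, sigma=330.0, noise=0.0, extent=2500.0,
             step=5.0, seed=0):
        return synth_ilm_profile(rim, amp, sigma, noise, extent, step,
                                 np.random.default_rng(seed))
    return make


@pytest.fixture
def noiseless_pit(gaussian_pit):
    return gaussian_pit()
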