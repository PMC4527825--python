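"""Deterministic synthetic fields for tests and examples.

Every fixture is generated programmatically: tanh slabs and kinks for
interface dynamics, detached blobs and tapered triangles for the morphology
classifier, and band-limited random fields for stencil/assembly oracles.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec, ScalarField

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "slab_vessel",
    "kink_1d",
    "blob",
    "finger",
    "triangle",
    "random_smooth",
)


def make_fixture(
    kind: str,
    grid: GridSpec,
    seed: int = 0,
    *,
    epsilon: float = 2.0,
    width: float = 10.0,
) -> ScalarField:
    """Build one synthetic phi field.

    kinds: ``slab_vessel`` (vertical slab of ``width`` at the left),
    ``kink_1d`` (equilibrium tanh profile along x, uniform in y), ``blob``
    (slab plus a detached disc), ``finger`` (slab plus an attached
    constant-width finger), ``triangle`` (slab plus a tapered triangular
    sprout), ``random_smooth`` (seeded band-limited field, zero mean).
    """
    X, Y = grid.coords()
    lx, ly = grid.extent
    x0, y0 = grid.origin
    sq2e = np.sqrt(2.0) * epsilon

    if kind == "slab_vessel":
        vals = np.tanh((x0 + width - X) / sq2e)
    elif kind == "kink_1d":
        vals = np.tanh((X - x0 - lx / 2.0) / sq2e)
    elif kind == "blob":
        slab = np.tanh((x0 + width - X) / sq2e)
        r = np.hypot(X - (x0 + lx * 0.6), Y - (y0 + ly / 2.0))
        disc = np.tanh((6.0 - r) / sq2e)
        vals = np.maximum(slab, disc)
    elif kind == "finger":
        slab = np.tanh((x0 + width - X) / sq2e)
        inside = (
            (X <= x0 + lx * 0.7)
            & (np.abs(Y - (y0 + ly / 2.0)) <= 4.0)
        )
        finger = np.where(inside, 1.0, -1.0)
        vals = np.maximum(slab, finger)
    elif kind == "triangle":
        slab = np.tanh((x0 + width - X) / sq2e)
        tip_x = x0 + lx * 0.75
        base_half, tip_half = 15.0, 3.0
        frac = np.clip((X - x0 - width) / (tip_x - x0 - width), 0.0, 1.0)
        half = base_half + (tip_half - base_half) * frac
        inside = (X <= tip_x) & (np.abs(Y - (y0 + ly / 2.0)) <= half)
        vals = np.maximum(slab, np.where(inside, 1.0, -1.0))
    elif kind == "random_smooth":
        rng = np.random.default_rng(seed)
        vals = np.zeros(grid.shape)
        # few low-order Fourier modes: smooth, non-trivial, deterministic
        for _ in range(6):
            kx = rng.integers(1, 4) * np.pi / lx
            ky = rng.integers(1, 4) * np.pi / ly
            amp = rng.normal(0, 0.3)
            ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
            vals += amp * np.cos(kx * (X - x0) + ph1) * np.cos(ky * (Y - y0) + ph2)
        vals -= vals.mean()
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected {FIXTURE_KINDS}")
    return ScalarField(grid, vals)
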