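"""Shared fixtures and random-model factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ckcoh.ar import ARModel
from ckcoh.bar import BARModel


def random_stable_ar_model(rng: np.random.Generator, order: int | None = None) -> ARModel:
    """AR model with poles sampled inside the unit circle (stable by design)."""
    if order is None:
        order = int(rng.integers(8, 15))
    poles: list[complex] = []
    remaining = order
    while remaining > 0:
        if remaining >= 2 and rng.random() < 0.8:
            mod = rng.uniform(0.3, 0.95)
            ang = rng.uniform(0.03, 0.47) * 2.0 * np.pi
            p = mod * np.exp(1j * ang)
            poles += [p, np.conj(p)]
            remaining -= 2
        else:
            poles.append(complex(rng.uniform(-0.9, 0.9)))
            remaining -= 1
    coeffs = np.poly(np.asarray(poles))  # z^p + c1 z^{p-1} + ...
    a = -np.real(coeffs[1:])
    return ARModel(
        a=a,
        order=order,
        sigma2_w=float(rng.uniform(0.5, 2.0)),
        series_mean=0.0,
        series_variance=1.0,
        mean_hp_s=1.0,
    )


def random_stable_bar_model(
    rng: np.random.Generator,
    order: int | None = None,
    latency: tuple[int, int] | None = None,
    target_radius: float | None = None,
) -> BARModel:
    """Random BAR model rescaled to a stable spectral radius.

    Scaling the lag-k matrices by c^-k divides every companion eigenvalue
    by c, so any draw can be normalised to the target radius exactly.
    """
    if order is None:
        order = int(rng.integers(5, 15))
    if latency is None:
        latency = [(0, 1), (1, 0), (1, 1)][int(rng.integers(3))]
    if target_radius is None:
        target_radius = rng.uniform(0.5, 0.95)
    k_xy, k_yx = latency
    coef = rng.normal(0.0, 0.5, size=(order + 1, 2, 2))
    coef /= (np.arange(order + 1) + 1.0)[:, None, None]
    coef[0] = 0.0
    if k_yx == 0:
        coef[0, 0, 1] = rng.normal(0.0, 0.5)
    if k_xy == 0:
        coef[0, 1, 0] = rng.normal(0.0, 0.5)
    if k_yx == 1:
        coef[0, 0, 1] = 0.0
    if k_xy == 1:
        coef[0, 1, 0] = 0.0

    model = BARModel(
        order=order,
        coef=coef,
        lambdas=(float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.5, 2.0))),
        latency=latency,
        n_samples=256,
        stable=True,
    )
    radius = np.abs(model.companion_eigenvalues()).max()
    if radius > 0:
        scale = radius / target_radius
        model.coef[1:] /= scale ** np.arange(1, order + 1)[:, None, None]
    assert np.abs(model.companion_eigenvalues()).max() < 1.0
    return model


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
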