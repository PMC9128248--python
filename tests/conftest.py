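"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def pmi_brute_force(counts: np.ndarray) -> float:
    """Brute-force PMI by direct summation of the defining formula.

    Takes a nonnegative (nx, ny, nz) count/probability table and evaluates
    D(p(x,y,z) || p*(x|z) p*(y|z) p(z)) with explicit loops, independent of
    the package's modular pipeline.
    """
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    nx, ny, nz = p.shape
    p_x = p.sum(axis=(1, 2))
    p_y = p.sum(axis=(0, 2))
    p_z = p.sum(axis=(0, 1))
    p_yz = p.sum(axis=0)          # [y, z]
    p_xz = p.sum(axis=1)          # [x, z]
    star_x = np.zeros((nx, nz))
    for x in range(nx):
        for z in range(nz):
            s = 0.0
            for y in range(ny):
                if p_yz[y, z] > 0:
                    s += (p[x, y, z] / p_yz[y, z]) * p_y[y]
            star_x[x, z] = s
    star_y = np.zeros((ny, nz))
    for y in range(ny):
        for z in range(nz):
            s = 0.0
            for x in range(nx):
                if p_xz[x, z] > 0:
                    s += (p[x, y, z] / p_xz[x, z]) * p_x[x]
            star_y[y, z] = s
    total = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if p[x, y, z] > 0:
                    q = star_x[x, z] * star_y[y, z] * p_z[z]
                    if q == 0:
                        return float("inf")
                    total += p[x, y, z] * np.log(p[x, y, z] / q)
    return total


def expand_counts(counts: np.ndarray):
    """Expand an integer count table into sample vectors whose empirical
    joint equals the table exactly (values are the bin indices)."""
    xs, ys, zs = [], [], []
    it = np.ndindex(counts.shape)
    for idx in it:
        c = int(counts[idx])
        xs += [idx[0]] * c
        ys += [idx[1]] * c
        zs += [idx[2]] * c
    return (np.array(xs, dtype=float), np.array(ys, dtype=float),
            np.array(zs, dtype=float))


def chain_samples(seed: int, n: int = 2000, noise_sd: float = 0.5):
    """Linear cascade X1 -> X2 -> X3 with unit coefficients plus an
    unrelated variable W."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, n)
    x2 = x1 + rng.normal(0, noise_sd, n)
    x3 = x2 + rng.normal(0, noise_sd, n)
    w = rng.normal(0, 1, n)
    return x1, x2, x3, w


@pytest.fixture
def chain_expr():
    """3-gene chain expression matrix (genes x samples)."""
    x1, x2, x3, _ = chain_samples(seed=7)
    return pd.DataFrame({"X1": x1, "X2": x2, "X3": x3}).T


@pytest.fixture
def small_clinical():
    """120-sample clinical table with exponential survival, no covariates."""
    rng = np.random.default_rng(42)
    times = rng.exponential(100.0, 120)
    events = (rng.random(120) > 0.2).astype(int)
    return pd.DataFrame({"time": times, "event": events},
                        index=[f"s{i:03d}" for i in range(120)])
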