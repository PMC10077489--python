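"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: the ring
profile oracle convolves an ideal circle with the PSF by dense numerical
summation, and the Gaussian-fit oracle is a lattice search over (center,
sigma) with closed-form linear solves for amplitude and baseline.
"""
from __future__ import annotations

import numpy as np
import pytest

from glxquant import peaks, profiles, synthetic


def numeric_ring_profile(rs, radius, sigma, n_theta=20000):
    """Oracle: intensity at distance r from the centre of an ideal circle of
    given radius convolved with a unit-sum 2D Gaussian PSF, computed by
    direct numerical summation over densely sampled circle points."""
    rs = np.atleast_1d(np.asarray(rs, dtype=float))
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    px = radius * np.cos(theta)
    py = radius * np.sin(theta)
    dl = 2 * np.pi * radius / n_theta
    out = np.empty_like(rs)
    for i, r in enumerate(rs):
        d2 = (r - px) ** 2 + py**2
        out[i] = np.sum(np.exp(-d2 / (2 * sigma**2))) / (2 * np.pi * sigma**2) * dl
    return out


def _best_center_for_sigmas(d, v, centers, sigmas):
    """For every (center, sigma) on the lattice, solve amplitude/baseline by
    linear least squares and return the lattice point minimising the RSS."""
    n = d.size
    sv = float(v.sum())
    best = (np.inf, np.nan, np.nan)
    for s in sigmas:
        g = np.exp(-((d[None, :] - centers[:, None]) ** 2) / (2 * s**2))
        sg = g.sum(axis=1)
        sgg = (g * g).sum(axis=1)
        sgv = g @ v
        det = n * sgg - sg**2
        det[det == 0] = np.nan
        amp = (n * sgv - sg * sv) / det
        base = (sv - amp * sg) / n
        rss = np.sum((v[None, :] - amp[:, None] * g - base[:, None]) ** 2, axis=1)
        i = int(np.nanargmin(rss))
        if rss[i] < best[0]:
            best = (rss[i], centers[i], s)
    return best


def grid_search_gaussian(distances, values, resolution=0.001):
    """Oracle: lattice search over (center, sigma) minimising the same RSS
    objective as the fit, coarse pass at 10x the resolution then a local
    refinement on the full-resolution lattice.  Returns (center, sigma)."""
    d = np.asarray(distances, dtype=float)
    v = np.asarray(values, dtype=float)
    step = d[1] - d[0]
    span = d[-1] - d[0]
    coarse = 10 * resolution
    centers = np.arange(d[0], d[-1] + coarse / 2, coarse)
    sigmas = np.arange(step, span + coarse / 2, coarse)
    _, c0, s0 = _best_center_for_sigmas(d, v, centers, sigmas)

    centers = np.arange(
        max(d[0], c0 - 1.5 * coarse), min(d[-1], c0 + 1.5 * coarse) + resolution / 2,
        resolution,
    )
    sigmas = np.arange(
        max(step, s0 - 1.5 * coarse), min(span, s0 + 1.5 * coarse) + resolution / 2,
        resolution,
    )
    _, c1, s1 = _best_center_for_sigmas(d, v, centers, sigmas)
    return c1, s1


@pytest.fixture(scope="session")
def default_truth():
    return synthetic.LoopTruth(
        radius_membrane=5.0,
        glx_offset=0.3,
        psf_sigma=0.1,
        pixel_size=0.05,
        noise_model="none",
        seed=0,
    )


@pytest.fixture(scope="session")
def default_loop(default_truth):
    return synthetic.make_loop_image(default_truth)


@pytest.fixture(scope="session")
def default_contour(default_loop):
    pair, resolved = default_loop
    return profiles.extract_contour(pair, resolved.center)


@pytest.fixture(scope="session")
def default_lines(default_contour):
    return profiles.place_lines_auto(default_contour)


@pytest.fixture(scope="session")
def default_measurements(default_loop, default_lines):
    pair, _ = default_loop
    return [
        peaks.measure_line(profiles.sample_profile(pair, ln), ln.line_id)
        for ln in default_lines
    ]
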