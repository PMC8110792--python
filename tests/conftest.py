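"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from gconequant.stripe_guidance import NeuriteTrace, SphereGeometry


def make_random_traces(rng: np.random.Generator, n_traces: int,
                       sphere: SphereGeometry, n_steps: int = 30,
                       step: float = 5.0, turn_sd: float = 0.4) -> list[NeuriteTrace]:
    """Smooth random polylines sprouting from the sphere rim (test data)."""
    traces = []
    for i in range(n_traces):
        a = rng.uniform(0, 2 * math.pi)
        x = sphere.center[0] + sphere.radius * math.cos(a)
        y = sphere.center[1] + sphere.radius * math.sin(a)
        heading = a
        verts = [(x, y)]
        for _ in range(n_steps):
            heading += rng.normal(0, turn_sd)
            x += step * math.cos(heading)
            y += step * math.sin(heading)
            verts.append((x, y))
        traces.append(NeuriteTrace(trace_id=i, vertices=np.array(verts)))
    return traces


def sholl_brute_force(traces, sphere, orientation, ring_spacing, n_rings):
    """Independent brute-force oracle: exhaustive quadratic root solving per
    segment and ring in a plain Python loop, with its own quadrant math."""
    cx, cy = sphere.center
    ox, oy = orientation
    phi = math.atan2(oy, ox)
    par = [0] * n_rings
    perp = [0] * n_rings
    for tr in traces:
        v = tr.vertices
        for i in range(len(v) - 1):
            ax = v[i, 0] - cx
            ay = v[i, 1] - cy
            dx = v[i + 1, 0] - v[i, 0]
            dy = v[i + 1, 1] - v[i, 1]
            A = dx * dx + dy * dy
            B = 2.0 * (ax * dx + ay * dy)
            C0 = ax * ax + ay * ay
            if A <= 0:
                continue
            for k in range(n_rings):
                r = sphere.radius + (k + 1) * ring_spacing
                C = C0 - r * r
                disc = B * B - 4.0 * A * C
                if disc <= 0:
                    continue
                s = math.sqrt(disc)
                for sign in (-1.0, 1.0):
                    t = (-B + sign * s) / (2.0 * A)
                    if 0.0 <= t < 1.0:
                        px = ax + t * dx
                        py = ay + t * dy
                        theta = math.atan2(py, px)
                        d = (theta - phi + math.pi / 2) % math.pi - math.pi / 2
                        if -math.pi / 4 <= d < math.pi / 4:
                            par[k] += 1
                        else:
                            perp[k] += 1
    return par, perp


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
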