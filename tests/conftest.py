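"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from paleoenamel.phantom import PhantomSpec, generate_phantom
from paleoenamel.volume_core import GreyLevelVolume


def brute_force_wilcoxon_p(differences) -> float:
    """Independent exact two-sided signed-rank p: own midranks, explicit
    iteration over every sign assignment.  Deliberately naive."""
    d = [float(x) for x in differences if x != 0]
    n = len(d)
    assert n >= 1, "oracle needs a nonzero difference"
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs(d[order[j + 1]]) == abs(d[order[i]]):
            j += 1
        mid = (i + 1 + j + 1) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    w_plus = sum(r for r, x in zip(ranks, d) if x > 0)
    w_minus = sum(r for r, x in zip(ranks, d) if x < 0)
    stat = min(w_plus, w_minus)
    total = sum(ranks)
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        t_plus = sum(r for s, r in zip(signs, ranks) if s)
        if min(t_plus, total - t_plus) <= stat + 1e-9:
            hits += 1
    return hits / 2.0**n


@pytest.fixture
def gradient_volume() -> GreyLevelVolume:
    """20x12x12 volume linear in z: value = 100 + 10 * z_index."""
    nz, ny, nx = 20, 12, 12
    z = np.arange(nz, dtype=float)
    values = np.broadcast_to((100.0 + 10.0 * z)[:, None, None], (nz, ny, nx)).copy()
    return GreyLevelVolume(values=values, voxel_size=np.full(3, 7.0))


@pytest.fixture
def sound_spec() -> PhantomSpec:
    return PhantomSpec(lesion_class="sound", noise_sd=0.0)


@pytest.fixture
def hypo_spec() -> PhantomSpec:
    return PhantomSpec(lesion_class="hypomineralised", deficit_mid=0.07, noise_sd=0.0)


@pytest.fixture
def hypo_phantom(hypo_spec):
    return generate_phantom(hypo_spec)
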