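"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (explicit offset enumeration, full
sign-assignment enumeration, from-definition sums) and never share code with
the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from odacs.imaging_io import BinaryMask, ImageVolume
from odacs.phantom import PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def shift_bool(a: np.ndarray, off) -> np.ndarray:
    """Shift a boolean array by an integer offset, zero-filling."""
    out = np.zeros_like(a)
    src = tuple(
        slice(max(-o, 0), a.shape[i] - max(o, 0)) for i, o in enumerate(off)
    )
    dst = tuple(
        slice(max(o, 0), a.shape[i] - max(-o, 0)) for i, o in enumerate(off)
    )
    if all(s.start < s.stop for s in src):
        out[dst] = a[src]
    return out


def brute_force_closing(mask: np.ndarray, offsets, pad: tuple[int, int, int]) -> np.ndarray:
    """Set-based closing: dilation then erosion over an infinite zero
    background, realized by padding with the element extent."""
    padded = np.pad(mask, [(p, p) for p in pad])
    dilated = np.zeros_like(padded)
    for off in offsets:
        dilated |= shift_bool(padded, off)
    eroded = np.ones_like(padded)
    for off in offsets:
        eroded &= shift_bool(dilated, tuple(-o for o in off))
    a, b, c = pad
    return eroded[a: padded.shape[0] - a or None,
                  b: padded.shape[1] - b or None,
                  c: padded.shape[2] - c or None]


def enumerate_ellipsoid_offsets(a: int, b: int, c: int) -> set[tuple[int, int, int]]:
    """All integer offsets inside the inclusive ellipsoid, by direct loop."""
    out = set()
    for dx in range(-a, a + 1):
        for dy in range(-b, b + 1):
            for dz in range(-c, c + 1):
                q = 0.0
                bad = False
                for d, s in ((dx, a), (dy, b), (dz, c)):
                    if s == 0:
                        if d != 0:
                            bad = True
                            break
                    else:
                        q += (d / s) ** 2
                if not bad and q <= 1.0:
                    out.add((dx, dy, dz))
    return out


def exact_wilcoxon_pvalue(d: np.ndarray, alternative: str) -> float:
    """One-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    assert np.all(d != 0) and np.unique(np.abs(d)).size == d.size
    ranks = rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    stats = []
    for signs in itertools.product((0, 1), repeat=len(d)):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.asarray(stats)
    if alternative == "less":
        return float(np.mean(stats <= observed))
    return float(np.mean(stats >= observed))


def brute_force_weighted_kappa(a, b, categories) -> float:
    """Quadratically weighted kappa summed pair-by-pair from the definition."""
    pos = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    n = len(a)

    def w(x, y):
        return (pos[x] - pos[y]) ** 2 / (k - 1) ** 2

    observed = sum(w(x, y) for x, y in zip(a, b)) / n
    expected = sum(w(x, y) for x in a for y in b) / n**2
    if expected == 0:
        return 1.0 if observed == 0 else float("nan")
    return 1.0 - observed / expected


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> BinaryMask:
    return BinaryMask(np.asarray(data, dtype=bool), spacing, origin)


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                value_kind="intensity") -> ImageVolume:
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin, value_kind=value_kind)


def random_blob_mask(rng: np.random.Generator, shape=(32, 32, 32), n_blobs=4,
                     spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    """A few random ellipsoidal blobs; denser structure than voxel noise."""
    data = np.zeros(shape, dtype=bool)
    idx = np.indices(shape).reshape(3, -1).T
    for _ in range(n_blobs):
        centre = rng.uniform(0.2, 0.8, size=3) * np.asarray(shape)
        semi = rng.uniform(2.0, 6.0, size=3)
        q = (((idx - centre) / semi) ** 2).sum(axis=1)
        sel = idx[q <= 1.0]
        data[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return BinaryMask(data, spacing)


@pytest.fixture(scope="session")
def phantom_half() -> "object":
    """A phantom with truth ratio 0.5, reused across read-only tests."""
    return generate_phantom(PhantomSpec(target_ratio=0.5, seed=7))


@pytest.fixture(scope="session")
def phantom_symmetric() -> "object":
    """A mirror-symmetric phantom (target ratio 1.0)."""
    return generate_phantom(PhantomSpec(target_ratio=1.0, seed=11))
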