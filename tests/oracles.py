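"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by the most literal method available —
explicit loops, exhaustive enumeration, or dense grid search — and never
shares code with the implementation path it checks.
"""

import itertools
import math

import numpy as np
from scipy.spatial.transform import Rotation


def loop_distance_covariance(a: np.ndarray, b: np.ndarray) -> float:
    """O(n^2) double-loop distance covariance: explicit double centering."""
    n = a.shape[0]
    da = np.zeros((n, n))
    db = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            da[i, j] = math.dist(a[i], a[j])
            db[i, j] = math.dist(b[i], b[j])

    def center(d):
        out = np.zeros_like(d)
        grand = d.mean()
        for i in range(n):
            for j in range(n):
                out[i, j] = d[i, j] - d[i].mean() - d[:, j].mean() + grand
        return out

    ca, cb = center(da), center(db)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += ca[i, j] * cb[i, j]
    return total / n**2


def loop_dicc(a: np.ndarray, b: np.ndarray) -> float:
    vab = loop_distance_covariance(a, b)
    vaa = loop_distance_covariance(a, a)
    vbb = loop_distance_covariance(b, b)
    return vab / math.sqrt(vaa * vbb)


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray, steps: int = 48) -> float:
    """Minimum RMSD over a dense Euler-angle grid of proper rotations.

    The optimal translation is the centroid match, so only rotations are
    searched (zyz Euler angles covering SO(3)).  Returns an upper bound on
    the true minimum, tight to the grid resolution.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    full = np.linspace(0.0, 2 * np.pi, steps, endpoint=False)
    half = np.linspace(0.0, np.pi, steps // 2 + 1)
    triplets = [[a, b, c] for a in full for b in half for c in full]
    matrices = Rotation.from_euler("zyz", triplets).as_matrix()
    rotated = np.einsum("mij,nj->mni", matrices, mob)
    rmsd = np.sqrt(((rotated - ref[None]) ** 2).sum(axis=(1, 2)) / mob.shape[0])
    return float(rmsd.min())


def loop_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Direct per-atom loop RMSD, no re-fitting."""
    total = 0.0
    for xa, xb in zip(coords_a, coords_b):
        total += sum((u - v) ** 2 for u, v in zip(xa, xb))
    return math.sqrt(total / len(coords_a))


def enumerate_isotopologues(
    counts: dict[str, int],
    abundances: dict[str, tuple[float, ...]],
    max_shift: int,
) -> np.ndarray:
    """Exact aggregated isotopologue distribution by exhaustive enumeration.

    For each element, every way of distributing its atoms over its isotopes
    is enumerated with its multinomial probability; element distributions
    are then combined by explicit dictionary convolution over nominal-mass
    shifts.  Independent of the implementation's vector convolution.
    """

    def element_distribution(n: int, probs: tuple[float, ...]) -> dict[int, float]:
        k = len(probs)
        dist: dict[int, float] = {}
        for combo in itertools.product(range(n + 1), repeat=k - 1):
            heavy = sum(combo)
            if heavy > n:
                continue
            occupancy = (n - heavy, *combo)
            coeff = math.factorial(n)
            for c in occupancy:
                coeff //= math.factorial(c)
            prob = coeff * math.prod(p**c for p, c in zip(probs, occupancy))
            shift = sum(offset * c for offset, c in enumerate(occupancy))
            if shift <= max_shift + 4:
                dist[shift] = dist.get(shift, 0.0) + prob
        return dist

    combined: dict[int, float] = {0: 1.0}
    for symbol, n in counts.items():
        elem = element_distribution(n, abundances[symbol])
        merged: dict[int, float] = {}
        for s1, p1 in combined.items():
            for s2, p2 in elem.items():
                if s1 + s2 <= max_shift + 4:
                    merged[s1 + s2] = merged.get(s1 + s2, 0.0) + p1 * p2
        combined = merged
    out = np.array([combined.get(k, 0.0) for k in range(max_shift)])
    return out / out.sum()
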