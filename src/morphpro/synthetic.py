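"""Seeded generators of protein-like (and deliberately broken) C-alpha chains.

These fixtures let the whole pipeline be exercised without any structure
downloads.  ``generate_chain`` grows a self-avoiding chain with exact
consecutive spacing and pseudo-bond angles drawn uniformly from a window,
with free dihedrals; rejection sampling enforces a steric clearance between
non-consecutive residues.  ``make_morph_pair`` produces a hinge (torsion)
motion: the segment past an interior pivot is rotated rigidly about the
incoming virtual bond, which preserves all bond lengths and angles exactly,
so both endpoints are protein-like by construction.

All randomness is driven by an explicit integer seed; equal seeds give
byte-identical chains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .io_structures import CaTrace
from .metrics import check_protein_like
from .oesp import ScoreParams

__all__ = ["ChainSpec", "generate_chain", "perturb_chain", "make_morph_pair"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ChainSpec:
    """Recipe for one synthetic chain.

    spacing is the exact consecutive C-alpha distance (3.8 A for a valid
    chain; values outside [3.7, 3.9] produce deliberately invalid ones);
    angle_low/high bound the sampled pseudo-bond angles in degrees;
    clearance is the minimum allowed distance between non-consecutive
    residues during growth (kept slightly above the 2.0 A clash limit so
    generated chains sit strictly inside the feasible region).
    """

    n: int = 30
    spacing: float = 3.8
    angle_low: float = 80.0
    angle_high: float = 110.0
    seed: int = 0
    clearance: float = 2.2

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 < self.angle_low < self.angle_high <= 180.0:
            raise ValueError("need 0 < angle_low < angle_high <= 180")


class ChainGenerationError(RuntimeError):
    """Rejection-sampling budget exhausted (pathological spec)."""


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def _grow(rng: np.random.Generator, spec: ChainSpec) -> np.ndarray | None:
    coords = np.zeros((spec.n, 3))
    coords[1] = (spec.spacing, 0.0, 0.0)
    for j in range(2, spec.n):
        placed = False
        for _ in range(200):
            theta = np.radians(rng.uniform(spec.angle_low, spec.angle_high))
            phi = rng.uniform(0.0, 2.0 * np.pi)
            d = coords[j - 1] - coords[j - 2]
            d /= np.linalg.norm(d)
            # orthonormal frame around the previous bond direction
            ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            e1 = np.cross(d, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(d, e1)
            # new bond makes the sampled vertex angle with the incoming bond
            new_dir = (-np.cos(theta) * d
                       + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))
            candidate = coords[j - 1] + spec.spacing * new_dir
            dists = np.linalg.norm(coords[: j - 1] - candidate, axis=1)
            if np.all(dists > spec.clearance):
                coords[j] = candidate
                placed = True
                break
        if not placed:
            return None
    return coords


def generate_chain(spec: ChainSpec) -> CaTrace:
    """Grow a self-avoiding chain matching the spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    sequence = _random_sequence(rng, spec.n)
    for _ in range(50):
        coords = _grow(rng, spec)
        if coords is not None:
            residue_ids = [("A", i + 1, "") for i in range(spec.n)]
            return CaTrace(coords, residue_ids, sequence)
    raise ChainGenerationError(
        f"could not grow a self-avoiding chain for {spec}; spec is likely pathological")


def perturb_chain(trace: CaTrace, sigma: float, seed: int = 0) -> CaTrace:
    """Add isotropic per-coordinate Gaussian noise of scale sigma (A).

    Emulates the geometric damage done by raw linear interpolation, which
    Proteinize is meant to repair.  sigma = 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return trace.with_coords(trace.coords.copy())
    rng = np.random.default_rng(seed)
    return trace.with_coords(trace.coords + rng.normal(0.0, sigma, trace.coords.shape))


def make_morph_pair(spec: ChainSpec, hinge_index: int | None = None,
                    hinge_angle_deg: float = 30.0, params: ScoreParams = ScoreParams(),
                    max_tries: int = 100) -> tuple[CaTrace, CaTrace]:
    """A start/end pair related by a rigid hinge (torsion) rotation.

    The chain segment past ``hinge_index`` is rotated by ``hinge_angle_deg``
    about the virtual bond entering the hinge.  The rotation is a rigid map
    fixing the hinge point and preserving the angle there, so the only way
    the end conformation can fail protein-likeness is a clash between the
    two arms; in that case a fresh base chain is drawn (up to
    ``max_tries``).
    """
    if hinge_index is None:
        hinge_index = spec.n // 2
    if not 1 <= hinge_index <= spec.n - 2:
        raise ValueError("hinge_index must be interior to the chain")
    for attempt in range(max_tries):
        chain = generate_chain(replace(spec, seed=spec.seed + attempt))
        coords = chain.coords
        pivot = coords[hinge_index]
        axis = pivot - coords[hinge_index - 1]
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.radians(hinge_angle_deg) * axis)
        end_coords = coords.copy()
        end_coords[hinge_index + 1:] = pivot + rot.apply(coords[hinge_index + 1:] - pivot)
        end = chain.with_coords(end_coords)
        if check_protein_like(end, params).all_pass and check_protein_like(chain, params).all_pass:
            return chain, end
    raise ChainGenerationError(
        f"hinge rotation kept clashing after {max_tries} re-draws (spec {spec})")
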