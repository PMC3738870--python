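"""The morph driver: iterate interpolation + Proteinize between two traces.

Given preprocessed (equal-length, superposed) start and end C-alpha traces,
the morph produces K protein-like intermediates.  At step k the current
conformation first moves a fraction of the way towards the end structure
(linear interpolation), and the resulting point sequence is then corrected
by Proteinize.  K defaults to the rounded largest per-residue C-alpha
displacement between the endpoints (e.g. a 15.2 A maximum movement gives
K = 15), so consecutive frames differ only slightly.

Proteinize first tries a lattice edge of 1.0 A; when no solution exists the
edge is retried at 1.5 A and then 2.0 A for that frame.  If the largest
edge also fails, the morph as a whole fails with a diagnostic naming the
frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_structures import CaTrace
from .oesp import ProteinizeResult, ScoreParams, proteinize
from .preprocessing import AlignedPair, rmsd

logger = logging.getLogger("morphpro")

__all__ = [
    "MorphConfig",
    "FrameDiagnostics",
    "MorphResult",
    "MorphInfeasibleError",
    "alpha_intermediate",
    "max_displacement",
    "choose_num_intermediates",
    "run_morph",
]


@dataclass(frozen=True)
class MorphConfig:
    """Tunable knobs of the morph pipeline.

    K
        Number of intermediates; ``None`` means automatic (rounded maximum
        C-alpha displacement, floored at 1).
    strategy
        Proteinize variant: "basic", "advanced" or "simplified" (default;
        also the variant used for all results of the original experiments).
    edge_schedule
        Ascending lattice edge lengths tried per frame until feasible.
    density
        Lattice points per linear Angstrom.
    schedule
        "remaining": at step k the target moves a fraction 1/(K - k + 2) of
        the *remaining* gap from the current conformation towards the end,
        so targets are evenly spaced and the last step lands adjacent to
        the end structure.  "fixed": target k is the alpha-intermediate of
        the original endpoints at alpha = k/(K + 1).
    rounding
        How the automatic K is rounded: "half_away" (round half away from
        zero) or "truncate".
    """

    K: Optional[int] = None
    strategy: str = "simplified"
    edge_schedule: tuple = (1.0, 1.5, 2.0)
    density: float = 6
    params: ScoreParams = field(default_factory=ScoreParams)
    schedule: str = "remaining"
    rounding: str = "half_away"

    def __post_init__(self) -> None:
        if self.K is not None and self.K < 1:
            raise ValueError("K must be >= 1 when explicit")
        if not self.edge_schedule or list(self.edge_schedule) != sorted(self.edge_schedule):
            raise ValueError("edge_schedule must be non-empty and ascending")
        if self.schedule not in ("remaining", "fixed"):
            raise ValueError("schedule must be 'remaining' or 'fixed'")
        if self.rounding not in ("half_away", "truncate"):
            raise ValueError("rounding must be 'half_away' or 'truncate'")


@dataclass
class FrameDiagnostics:
    """Per-intermediate record: which lattice edge succeeded and at what score."""

    frame: int                 # 1..K
    total_score: float
    edge_length: float
    feasible: bool
    target_rmsd_to_end: float  # RMSD of the interpolation target to the end
    frame_rmsd_to_end: float   # RMSD of the corrected frame to the end


@dataclass
class MorphResult:
    """Ordered frames [start, P_1, ..., P_K, end] plus per-frame diagnostics."""

    frames: list
    diagnostics: list
    config: MorphConfig
    num_intermediates: int


class MorphInfeasibleError(RuntimeError):
    """No protein-like correction exists at the largest lattice edge."""

    def __init__(self, frame: int, edge_length: float):
        self.frame = frame
        self.edge_length = edge_length
        super().__init__(
            f"no protein-like correction found for intermediate {frame} even at "
            f"lattice edge {edge_length:g} A; the morph cannot be produced"
        )


def _coords(x) -> np.ndarray:
    return np.asarray(getattr(x, "coords", x), dtype=float)


def alpha_intermediate(p: np.ndarray, p_prime: np.ndarray, alpha: float) -> np.ndarray:
    """Pointwise convex combination (1 - alpha) * P + alpha * P'."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    a, b = _coords(p), _coords(p_prime)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (1.0 - alpha) * a + alpha * b


def max_displacement(start, end) -> float:
    """Largest per-residue C-alpha movement between two conformations, in A."""
    a, b = _coords(start), _coords(end)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.max(np.linalg.norm(a - b, axis=1)))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def choose_num_intermediates(start, end, rounding: str = "half_away") -> int:
    """K = rounded maximum C-alpha displacement, floored at 1.

    A 15.2 A maximum movement gives K = 15.  ``rounding="truncate"`` drops
    the fractional part instead of rounding it.
    """
    disp = max_displacement(start, end)
    k = _round_half_away(disp) if rounding == "half_away" else int(disp)
    return max(1, k)


def _proteinize_with_retries(points: np.ndarray, config: MorphConfig,
                             broken_edge, broken_angle, frame: int) -> ProteinizeResult:
    result: ProteinizeResult | None = None
    for edge in config.edge_schedule:
        result = proteinize(
            points, strategy=config.strategy, params=config.params,
            edge_length=edge, density=config.density,
            broken_edge=broken_edge, broken_angle=broken_angle,
        )
        if result.feasible:
            return result
        logger.info("frame %d infeasible at lattice edge %.2f A, retrying", frame, edge)
    raise MorphInfeasibleError(frame, config.edge_schedule[-1])


def run_morph(start: CaTrace, end: CaTrace, config: MorphConfig = MorphConfig(),
              pair: Optional[AlignedPair] = None) -> MorphResult:
    """Generate K protein-like intermediates between two superposed traces.

    ``pair`` (when preprocessing involved an alignment) supplies the
    chain-break flags that free the corresponding bond and angle windows;
    without it all positions are treated as continuous.
    """
    if len(start) != len(end):
        raise ValueError("start and end must have equal length (run preprocessing first)")
    broken_edge = pair.broken_edge if pair is not None else None
    broken_angle = pair.broken_angle if pair is not None else None
    k_total = config.K if config.K is not None else choose_num_intermediates(
        start, end, config.rounding)
    end_coords = _coords(end)
    start_coords = _coords(start)
    current = start_coords
    frames: list[CaTrace] = [start]
    diagnostics: list[FrameDiagnostics] = []
    for k in range(1, k_total + 1):
        if config.schedule == "remaining":
            target = alpha_intermediate(current, end_coords, 1.0 / (k_total - k + 2))
        else:
            target = alpha_intermediate(start_coords, end_coords, k / (k_total + 1.0))
        result = _proteinize_with_retries(target, config, broken_edge, broken_angle, k)
        current = result.points
        frames.append(start.with_coords(current))
        diagnostics.append(FrameDiagnostics(
            frame=k,
            total_score=result.total_score,
            edge_length=result.edge_length,
            feasible=result.feasible,
            target_rmsd_to_end=rmsd(target, end_coords),
            frame_rmsd_to_end=rmsd(current, end_coords),
        ))
        logger.info("frame %d/%d: edge %.2f A, score %.3f", k, k_total,
                    result.edge_length, result.total_score)
    frames.append(end)
    return MorphResult(frames=frames, diagnostics=diagnostics, config=config,
                       num_intermediates=k_total)
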