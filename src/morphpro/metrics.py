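"""Protein-likeness validation and RMSD trajectory profiles.

``check_protein_like`` reports, for one trace, all three criteria that
define a protein-like C-alpha chain: consecutive distances in
[3.7, 3.9] A, interior pseudo-bond angles in [70, 120] degrees, and no two
non-consecutive residues closer than 2.0 A.  ``trajectory_rmsd_profile``
reproduces the evaluation used on real morphs: the RMSD of every frame,
after optimal superposition, to each of a set of reference structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .oesp import EPS, ScoreParams, vertex_angle
from .preprocessing import kabsch_superpose

__all__ = ["ProteinLikenessReport", "check_protein_like", "trajectory_rmsd_profile"]


@dataclass
class ProteinLikenessReport:
    """Full per-criterion report for one trace.

    ``angles[j]`` is NaN at the termini (no angle defined there);
    ``clash_pairs`` lists (i, j, distance) for non-consecutive pairs closer
    than the clash distance z.  Positions whose edge/angle is flagged as a
    chain break are excluded from the pass checks.
    """

    edge_distances: np.ndarray
    angles: np.ndarray
    clash_pairs: list
    bad_edges: list
    bad_angles: list
    pass_equidistant: bool
    pass_angles: bool
    pass_clash: bool
    params: ScoreParams = field(default_factory=ScoreParams)

    @property
    def all_pass(self) -> bool:
        return self.pass_equidistant and self.pass_angles and self.pass_clash

    def as_rows(self, label: str = "") -> list[dict]:
        """Flatten to rows suitable for a TSV report."""
        rows = [
            {"structure": label, "criterion": "equidistant", "passed": self.pass_equidistant,
             "violations": len(self.bad_edges),
             "detail": ";".join(f"edge {j}: {self.edge_distances[j]:.3f}A" for j in self.bad_edges)},
            {"structure": label, "criterion": "angles", "passed": self.pass_angles,
             "violations": len(self.bad_angles),
             "detail": ";".join(f"pos {j}: {self.angles[j]:.1f}deg" for j in self.bad_angles)},
            {"structure": label, "criterion": "clash", "passed": self.pass_clash,
             "violations": len(self.clash_pairs),
             "detail": ";".join(f"({i},{j}): {d:.2f}A" for i, j, d in self.clash_pairs)},
        ]
        return rows


def check_protein_like(trace, params: ScoreParams = ScoreParams(),
                       broken_edge=None, broken_angle=None) -> ProteinLikenessReport:
    """Evaluate all three protein-likeness criteria for one trace."""
    coords = np.asarray(getattr(trace, "coords", trace), dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 points")
    be = np.zeros(n - 1, bool) if broken_edge is None else np.asarray(broken_edge, bool)
    ba = np.zeros(n, bool) if broken_angle is None else np.asarray(broken_angle, bool).copy()
    ba[0] = ba[-1] = True

    diffs = np.diff(coords, axis=0)
    edge_distances = np.linalg.norm(diffs, axis=1)
    in_window = (edge_distances >= params.dist_low - EPS) & (edge_distances <= params.dist_high + EPS)
    bad_edges = [int(j) for j in np.nonzero(~in_window & ~be)[0]]

    angles = np.full(n, np.nan)
    bad_angles: list[int] = []
    for j in range(1, n - 1):
        try:
            angles[j] = vertex_angle(coords[j - 1], coords[j], coords[j + 1])
        except ValueError:
            angles[j] = np.nan
            if not ba[j]:
                bad_angles.append(j)
            continue
        if not ba[j] and not (params.angle_low - EPS <= angles[j] <= params.angle_high + EPS):
            bad_angles.append(j)

    tree = cKDTree(coords)
    clash_pairs = []
    for i, j in sorted(tree.query_pairs(r=params.clash_dist - EPS)):
        if abs(i - j) >= 2:
            clash_pairs.append((int(i), int(j), float(np.linalg.norm(coords[i] - coords[j]))))

    return ProteinLikenessReport(
        edge_distances=edge_distances,
        angles=angles,
        clash_pairs=clash_pairs,
        bad_edges=bad_edges,
        bad_angles=bad_angles,
        pass_equidistant=len(bad_edges) == 0,
        pass_angles=len(bad_angles) == 0,
        pass_clash=len(clash_pairs) == 0,
        params=params,
    )


def trajectory_rmsd_profile(frames: Sequence, references) -> pd.DataFrame:
    """RMSD of each frame to each reference, after Kabsch superposition.

    ``frames`` is a sequence of traces/coordinate arrays (e.g.
    ``MorphResult.frames``); ``references`` is a mapping label -> trace or a
    sequence of (label, trace) pairs.  Returns a DataFrame indexed by frame
    number with one column per reference label.
    """
    if hasattr(references, "items"):
        ref_items = list(references.items())
    else:
        ref_items = list(references)
    data = {}
    for label, ref in ref_items:
        ref_coords = np.asarray(getattr(ref, "coords", ref), dtype=float)
        column = []
        for frame in frames:
            coords = np.asarray(getattr(frame, "coords", frame), dtype=float)
            if coords.shape != ref_coords.shape:
                raise ValueError(
                    f"reference {label!r} has {len(ref_coords)} residues, frame has {len(coords)}")
            _, fit = kabsch_superpose(coords, ref_coords)
            column.append(fit)
        data[str(label)] = column
    profile = pd.DataFrame(data)
    profile.index.name = "frame"
    return profile
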