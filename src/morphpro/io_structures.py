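"""Read C-alpha traces from PDB files and write morphs as multi-model PDB.

The whole morphing pipeline models a protein chain as its ordered C-alpha
trace: one 3-D point per residue, plus the residue identity needed to write
the result back out.  Parsing goes through :mod:`gemmi`; writing is done with
explicit fixed-column formatting so that output is byte-stable (occupancy
1.00, B-factor 0.00, element " C" on every record).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import gemmi
import numpy as np

logger = logging.getLogger("morphpro")

__all__ = [
    "CaTrace",
    "PdbError",
    "PdbParseError",
    "NoCaAtomsError",
    "read_ca_trace",
    "read_ca_traces",
    "write_morph_pdb",
]


class PdbError(Exception):
    """Base class for structure I/O problems."""


class PdbParseError(PdbError):
    """The input could not be parsed as PDB text."""


class NoCaAtomsError(PdbError):
    """No usable CA atoms were found in the requested chain."""


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {one: three for three, one in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


@dataclass
class CaTrace:
    """An ordered C-alpha trace: the 3 x n coordinate matrix of a chain.

    Parameters
    ----------
    coords : (n, 3) float array
        C-alpha positions in Angstrom, in chain order.
    residue_ids : list of (chain_id, residue_number, insertion_code)
        Identity of each residue, used when writing PDB output and when
        deciding chain continuity after alignment restriction.
    sequence : str
        One-letter amino-acid sequence, length n.
    """

    coords: np.ndarray
    residue_ids: list = field(default_factory=list)
    sequence: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        n = len(self.coords)
        if not self.residue_ids:
            self.residue_ids = [("A", i + 1, "") for i in range(n)]
        if not self.sequence:
            self.sequence = "A" * n
        if not (len(self.residue_ids) == len(self.sequence) == n):
            raise ValueError("coords, residue_ids and sequence must have equal length")
        if n < 2:
            raise ValueError("a CA trace needs at least 2 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n(self) -> int:
        return len(self.coords)

    def with_coords(self, coords: np.ndarray) -> "CaTrace":
        """Same residues, new coordinates."""
        return CaTrace(np.asarray(coords, dtype=float), list(self.residue_ids), self.sequence)

    def subset(self, indices: Sequence[int]) -> "CaTrace":
        """Trace restricted to the given positions (in the given order)."""
        idx = list(indices)
        return CaTrace(
            self.coords[idx],
            [self.residue_ids[i] for i in idx],
            "".join(self.sequence[i] for i in idx),
        )


def _source_to_text(source: Union[str, Path, IO[str]]) -> tuple[str, str]:
    """Return (pdb_text, display_name) for a path, text stream, or PDB string."""
    if hasattr(source, "read"):
        return source.read(), getattr(source, "name", "<stream>")
    if isinstance(source, Path):
        return source.read_text(), str(source)
    if isinstance(source, str):
        # A multi-line string is PDB content; a single line is a file path.
        if "\n" in source:
            return source, "<string>"
        return Path(source).read_text(), source
    raise TypeError(f"unsupported PDB source: {type(source)!r}")


def _residue_one_letter(name: str) -> str:
    if name in _THREE_TO_ONE:
        return _THREE_TO_ONE[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.one_letter_code.isalpha():
        return info.one_letter_code.upper()
    return "X"


def _extract_trace(model: gemmi.Model, chain: str | None, name: str) -> CaTrace:
    chains = [ch.name for ch in model]
    if chain is None:
        if len(set(chains)) > 1:
            logger.warning(
                "%s has chains %s; no chain requested, using first chain %r",
                name, sorted(set(chains)), chains[0] if chains else None,
            )
        selected = [model[0]] if len(model) else []
    else:
        selected = [ch for ch in model if ch.name == chain]
    coords: list[list[float]] = []
    residue_ids: list[tuple[str, int, str]] = []
    seq: list[str] = []
    for ch in selected:
        for res in ch:
            if res.het_flag != "A":  # skip HETATM (modified residues, ligands)
                continue
            ca = None
            for atom in res:
                if atom.name == "CA" and atom.element != gemmi.Element("Ca"):
                    ca = atom  # first-listed altloc wins
                    break
            if ca is None:
                continue
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            icode = res.seqid.icode.strip()
            residue_ids.append((ch.name, res.seqid.num, icode))
            seq.append(_residue_one_letter(res.name))
    if not coords:
        where = f"chain {chain}" if chain is not None else "any chain"
        raise NoCaAtomsError(f"no CA atoms in {where} of {name}")
    if len(coords) < 2:
        raise PdbError(f"{name}: fewer than 2 CA residues in {'chain ' + chain if chain else 'first chain'}")
    return CaTrace(np.array(coords, dtype=float), residue_ids, "".join(seq))


def read_ca_traces(source: Union[str, Path, IO[str]], chain: str | None = None) -> list[CaTrace]:
    """Read one CaTrace per MODEL from PDB text (path, stream, or string)."""
    text, name = _source_to_text(source)
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PdbParseError(f"cannot parse {name} as PDB: {exc}") from exc
    if len(structure) == 0:
        raise PdbParseError(f"{name}: no models found in PDB input")
    return [_extract_trace(model, chain, name) for model in structure]


def read_ca_trace(source: Union[str, Path, IO[str]], chain: str | None = None) -> CaTrace:
    """Read the CA trace of the first model (see :func:`read_ca_traces`)."""
    return read_ca_traces(source, chain=chain)[0]


def write_morph_pdb(frames: Iterable[CaTrace]) -> str:
    """Serialize frames as a multi-model, CA-only PDB string.

    One MODEL/ENDMDL block per frame, model numbers 1..K+2, fixed occupancy
    1.00 and B-factor 0.00 so identical inputs give identical bytes.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    n = len(frames[0])
    for k, fr in enumerate(frames):
        if len(fr) != n:
            raise ValueError(f"frame {k} has {len(fr)} residues, expected {n}")
        if fr.residue_ids != frames[0].residue_ids:
            raise ValueError(f"frame {k} has residue ids inconsistent with frame 0")
    lines: list[str] = []
    for m, fr in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for serial, ((ch, num, icode), aa, (x, y, z)) in enumerate(
            zip(fr.residue_ids, fr.sequence, fr.coords), start=1
        ):
            res3 = _ONE_TO_THREE.get(aa, "UNK")
            lines.append(
                f"ATOM  {serial:5d}  CA  {res3:>3s} {(ch or 'A')[:1]:1s}"
                f"{num:4d}{(icode or ' ')[:1]:1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {'C':>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_morph_pdb_file(frames: Iterable[CaTrace], path: Union[str, Path]) -> None:
    """Write :func:`write_morph_pdb` output to a file."""
    Path(path).write_text(write_morph_pdb(frames))
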