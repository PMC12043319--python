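"""Topology/coordinate model, PDB and XYZ readers/writers, atom selections,
and thermal velocity initialization.

Coordinates are Å, velocities Å/ps, masses amu, times ps. Atom indexing is
0-based internally; residue ids keep the (1-based) values of the source file,
and ``resid`` ranges in the selection language are inclusive on both ends.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ELEMENT_MASSES, KB_AKMA
from .errors import (
    CongruenceError,
    EmptyInputError,
    FormatError,
    SelectionError,
    SelectionParseError,
)

__all__ = [
    "Topology",
    "WalkerState",
    "AtomSelection",
    "Trajectory",
    "read_pdb",
    "write_pdb",
    "read_xyz_traj",
    "write_xyz_traj",
    "select",
    "maxwell_boltzmann_velocities",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Topology:
    """Static per-atom metadata for a system of N atoms."""

    atom_names: list[str]
    elements: list[str]
    residue_names: list[str]
    residue_ids: np.ndarray  # int, as in the source file (typically 1-based)
    chain_ids: list[str]
    masses: np.ndarray  # amu

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.atom_names)
        if n < 1:
            raise EmptyInputError("topology must contain at least one atom")
        for name, seq in [
            ("elements", self.elements),
            ("residue_names", self.residue_names),
            ("chain_ids", self.chain_ids),
        ]:
            if len(seq) != n:
                raise CongruenceError(f"{name} has length {len(seq)}, expected {n}")
        if self.residue_ids.shape != (n,) or self.masses.shape != (n,):
            raise CongruenceError("residue_ids/masses shape mismatch with atom count")
        if not np.all(self.masses > 0):
            raise ValueError("all atomic masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def __len__(self) -> int:
        return self.n_atoms


@dataclass
class AtomSelection:
    """An ordered, duplicate-free set of 0-based atom indices."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise SelectionError(f"selection {self.label!r} is empty")
        if len(np.unique(self.indices)) != len(self.indices):
            raise SelectionError(f"selection {self.label!r} contains duplicates")
        if np.any(self.indices < 0):
            raise SelectionError(f"selection {self.label!r} has negative indices")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class WalkerState:
    """Coordinates + velocities + clock of one replica at one instant.

    This is the unit of continuation: a supervised protocol extends the
    productive walker from exactly this state, velocities included.
    """

    coordinates: np.ndarray  # (N, 3) Å
    velocities: np.ndarray | None = None  # (N, 3) Å/ps
    box: np.ndarray | None = None  # (3,) Å
    time: float = 0.0  # ps since protocol start

    def __post_init__(self) -> None:
        self.coordinates = np.array(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise CongruenceError("coordinates must have shape (N, 3)")
        if self.velocities is not None:
            self.velocities = np.array(self.velocities, dtype=float)
            if self.velocities.shape != self.coordinates.shape:
                raise CongruenceError("velocities shape differs from coordinates")
            if not np.all(np.isfinite(self.velocities)):
                raise ValueError("velocities contain non-finite values")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.time < 0:
            raise ValueError("time must be >= 0")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "WalkerState":
        return WalkerState(
            coordinates=self.coordinates.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            box=None if self.box is None else np.array(self.box, dtype=float),
            time=self.time,
        )


@dataclass
class Trajectory:
    """An ordered sequence of snapshots with strictly increasing times."""

    frames: list[WalkerState] = field(default_factory=list)
    frame_interval: float = 0.0  # ps; 0 when irregular/unknown

    def __post_init__(self) -> None:
        if self.frames:
            n = self.frames[0].n_atoms
            for f in self.frames:
                if f.n_atoms != n:
                    raise CongruenceError("all frames must have the same atom count")
            times = self.times
            if len(times) > 1 and not np.all(np.diff(times) > 0):
                raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def coordinates(self) -> np.ndarray:
        """All frame coordinates stacked as (n_frames, N, 3)."""
        return np.stack([f.coordinates for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def extend(self, other: "Trajectory", skip_first: bool = False) -> None:
        """Append frames of ``other``; with ``skip_first`` drop its leading
        frame (used when it duplicates this trajectory's final frame)."""
        new = other.frames[1:] if skip_first else other.frames
        merged = Trajectory(self.frames + [f for f in new], self.frame_interval)
        self.frames = merged.frames


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

_TWO_LETTER = {e for e in ELEMENT_MASSES if len(e) == 2}


def _infer_element(raw_name: str, element_field: str) -> str:
    """Element from the element column, falling back to atom-name heuristics.

    ``raw_name`` is the 4-character name field. PDB convention left-pads
    one-letter-element names (" CA " is an alpha carbon) while two-letter
    elements start in the first column ("CA  " is calcium); the heuristic
    honors that before falling back to the first letter.
    """
    el = element_field.strip().upper()
    if el in ELEMENT_MASSES:
        return el
    stripped = re.sub(r"[\d\s]", "", raw_name).upper()
    starts_col13 = len(raw_name) >= 1 and raw_name[0] not in (" ", "")
    if starts_col13 and stripped[:2] in _TWO_LETTER:
        return stripped[:2]
    if stripped[:1] in ELEMENT_MASSES:
        return stripped[:1]
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2]
    raise KeyError(raw_name)


def read_pdb(path) -> tuple[Topology, np.ndarray]:
    """Read ATOM/HETATM records of a PDB file.

    Returns the topology and an (N, 3) coordinate array in Å. Altloc codes
    other than blank/'A' are skipped with a warning; insertion codes are
    rejected. Masses come from the bundled element table.
    """
    atom_names, elements, res_names, res_ids, chains, masses = [], [], [], [], [], []
    coords = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise FormatError(f"line {lineno}: truncated ATOM record")
            altloc = line[16]
            if altloc not in (" ", "A"):
                warnings.warn(
                    f"line {lineno}: skipping altloc {altloc!r} record", stacklevel=2
                )
                continue
            icode = line[26]
            if icode != " ":
                raise FormatError(f"line {lineno}: insertion codes are not supported")
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                resid = int(line[22:26])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: unparsable numeric field: {exc}") from exc
            name = line[12:16].strip()
            element_field = line[76:78] if len(line) >= 78 else ""
            try:
                element = _infer_element(line[12:16], element_field)
            except KeyError:
                raise FormatError(
                    f"line {lineno}: cannot infer element for atom {name!r}"
                ) from None
            atom_names.append(name)
            elements.append(element)
            res_names.append(line[17:20].strip())
            res_ids.append(resid)
            chains.append(line[21].strip() or "A")
            masses.append(ELEMENT_MASSES[element])
            coords.append((x, y, z))
    if not coords:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    topology = Topology(
        atom_names=atom_names,
        elements=elements,
        residue_names=res_names,
        residue_ids=np.array(res_ids),
        chain_ids=chains,
        masses=np.array(masses),
    )
    return topology, np.array(coords, dtype=float)


def write_pdb(topology: Topology, coordinates: np.ndarray, path) -> None:
    """Write fixed-column PDB ATOM records (v3.3 layout) plus END."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (topology.n_atoms, 3):
        raise CongruenceError(
            f"coordinates shape {coordinates.shape} does not match "
            f"topology with {topology.n_atoms} atoms"
        )
    if np.any(np.abs(coordinates) >= 10000):
        raise FormatError("coordinate magnitude >= 10000 Å overflows PDB columns")
    with open(path, "w") as fh:
        for i in range(topology.n_atoms):
            name = topology.atom_names[i]
            # PDB name column convention: 1-letter elements start at col 14
            pname = f" {name:<3s}" if len(name) < 4 and len(topology.elements[i]) == 1 else f"{name:<4s}"
            x, y, z = coordinates[i]
            fh.write(
                f"ATOM  {i + 1:>5d} {pname}"
                f" {topology.residue_names[i]:<3s} {topology.chain_ids[i]:1s}"
                f"{topology.residue_ids[i]:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {topology.elements[i]:>2s}\n"
            )
        fh.write("END\n")


# --------------------------------------------------------------------------
# multi-frame XYZ with "t=<ps>" comment convention
# --------------------------------------------------------------------------

def read_xyz_traj(path) -> Trajectory:
    """Read a multi-frame XYZ file; the comment line carries ``t=<ps>``."""
    frames: list[WalkerState] = []
    names_ref: list[str] | None = None
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise EmptyInputError(f"{path}: empty XYZ file")
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"line {i + 1}: expected atom count") from exc
        if i + 1 + count >= len(lines) + 1 and count > 0:
            pass
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = re.search(r"t\s*=\s*([-+0-9.eE]+)", comment)
        t = float(m.group(1)) if m else float(frame_no)
        block = lines[i + 2 : i + 2 + count]
        if len(block) < count:
            raise FormatError(f"frame {frame_no}: truncated (expected {count} atoms)")
        names, xyz = [], []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(f"line {i + 3 + j}: expected 'name x y z'")
            names.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if names_ref is None:
            names_ref = names
        elif len(names) != len(names_ref):
            raise FormatError(f"frame {frame_no}: inconsistent atom count")
        frames.append(WalkerState(coordinates=np.array(xyz), time=t))
        i += 2 + count
        frame_no += 1
    if not frames:
        raise EmptyInputError(f"{path}: no frames found")
    interval = frames[1].time - frames[0].time if len(frames) > 1 else 0.0
    return Trajectory(frames=frames, frame_interval=interval)


def write_xyz_traj(traj: Trajectory, path, atom_names: list[str] | None = None) -> None:
    """Write a Trajectory as multi-frame XYZ, 6-decimal coordinates."""
    if traj.n_frames == 0:
        raise EmptyInputError("cannot write an empty trajectory")
    n = traj.frames[0].n_atoms
    names = atom_names if atom_names is not None else ["X"] * n
    if len(names) != n:
        raise CongruenceError("atom_names length does not match frame atom count")
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{n}\n")
            fh.write(f"t={frame.time:.6f}\n")
            for name, (x, y, z) in zip(names, frame.coordinates):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# --------------------------------------------------------------------------
# selection mini-language
# --------------------------------------------------------------------------
#
# grammar:  expr    := term ("or" term)*
#           term    := factor ("and" factor)*
#           factor  := "not" factor | "(" expr ")" | primitive
#           primitive := "chain" ID | "name" ID | "resid" RANGE | "index" RANGE
#           RANGE   := INT | INT "-" INT            (inclusive on both ends)

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, expression: str, topology: Topology):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.top = topology

    def _peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self):
        if self.pos >= len(self.tokens):
            raise SelectionParseError("unexpected end of expression", len(self.expression))
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._expr()
        if self.pos < len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise SelectionParseError(f"unexpected token {tok!r}", at)
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek() == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self._peek() == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok = self._peek()
        if tok == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            mask = self._expr()
            closing, at = self._next()
            if closing != ")":
                raise SelectionParseError("expected ')'", at)
            return mask
        return self._primitive()

    def _parse_range(self, text: str, at: int) -> tuple[int, int]:
        m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", text)
        if not m:
            raise SelectionParseError(f"expected integer or range, got {text!r}", at)
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) is not None else a
        return a, b

    def _primitive(self) -> np.ndarray:
        tok, at = self._next()
        if tok == "chain":
            arg, _ = self._next()
            return np.array([c == arg for c in self.top.chain_ids])
        if tok == "name":
            arg, _ = self._next()
            return np.array([n == arg for n in self.top.atom_names])
        if tok == "resname":
            arg, _ = self._next()
            return np.array([r == arg for r in self.top.residue_names])
        if tok == "resid":
            arg, argat = self._next()
            a, b = self._parse_range(arg, argat)
            return (self.top.residue_ids >= a) & (self.top.residue_ids <= b)
        if tok == "index":
            arg, argat = self._next()
            a, b = self._parse_range(arg, argat)
            idx = np.arange(self.top.n_atoms)
            return (idx >= a) & (idx <= b)
        raise SelectionParseError(f"unknown keyword {tok!r}", at)


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression against a topology.

    Supported terms: ``chain <id>``, ``name <atomname>``, ``resname <res>``,
    ``resid <a>[-<b>]``, ``index <a>[-<b>]``, combined with ``and``, ``or``,
    ``not`` and parentheses. Ranges are inclusive. The result is ordered by
    ascending atom index.
    """
    if not expression.strip():
        raise SelectionParseError("empty expression", 0)
    mask = _Parser(expression, topology).parse()
    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise SelectionError(f"expression {expression!r} selects no atoms")
    return AtomSelection(indices=indices, label=expression)


# --------------------------------------------------------------------------
# thermal velocities
# --------------------------------------------------------------------------

def maxwell_boltzmann_velocities(
    topology: Topology, temperature: float, seed: int
) -> np.ndarray:
    """Draw velocities (Å/ps) from the Maxwell–Boltzmann distribution.

    Each Cartesian component of atom i is normal with zero mean and variance
    k_B·T/m_i. Deterministic for a fixed seed. T must be strictly positive:
    supervised restarts require thermal velocities.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0 for velocity initialization")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB_AKMA * temperature / topology.masses)
    return rng.standard_normal((topology.n_atoms, 3)) * sigma[:, None]
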