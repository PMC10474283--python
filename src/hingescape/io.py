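"""Structures, ensembles, and multi-frame coordinate I/O.

Two on-disk formats are supported:

* PDB (``ATOM``/``HETATM``/``MODEL``/``ENDMDL``/``TER``/``END``), fixed
  columns, 3-decimal coordinates in Å.  One frame per ``MODEL`` block;
  a file without ``MODEL`` records is a single frame.
* A whitespace-separated multi-frame XYZ dialect: per frame, a line
  ``N``, a comment line ``t=<ps>``, then N lines
  ``name resname resid x y z``.

Residue IDs are taken verbatim from the file (1-based, as in mature-
sequence numbering conventions) and are never renumbered.  Atom indices
used internally are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import infer_element, mass_of


class ParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class FormatError(ValueError):
    """Raised when a structure cannot be written in the requested format."""


@dataclass
class Structure:
    """A fixed atom topology with one set of coordinates.

    All per-atom fields are numpy arrays of equal length N; coordinates
    are in Å and masses (Da) are derived from the element.
    """

    serial: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    residue_name: np.ndarray
    residue_id: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.serial = np.asarray(self.serial, dtype=np.int64)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.residue_id = np.asarray(self.residue_id, dtype=np.int64)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.serial), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{len(self.serial)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure")
        if self.masses is None:
            self.masses = np.array([mass_of(e) for e in self.element])
        else:
            self.masses = np.asarray(self.masses, dtype=np.float64)
        if np.any(self.masses <= 0):
            raise ValueError("non-positive atomic mass")

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure carrying different coordinates."""
        return Structure(
            self.serial, self.atom_name, self.element, self.residue_name,
            self.residue_id, self.chain_id, np.asarray(coords, dtype=np.float64),
            self.masses,
        )

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_id, residue_name) keys."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, n in zip(self.chain_id, self.residue_id, self.residue_name):
            seen.setdefault((str(c), int(r), str(n)), None)
        return list(seen)


@dataclass
class Ensemble:
    """A topology plus F frames of coordinates (Å), with optional times (ps)."""

    topology: Structure
    coords: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frame array shape {self.coords.shape} inconsistent with "
                f"{self.topology.n_atoms}-atom topology"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in ensemble")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=np.float64)
            if self.times.shape != (self.coords.shape[0],):
                raise ValueError("times length does not match frame count")
            if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def parse_structure(text: str) -> Ensemble:
    """Parse PDB-format text into an :class:`Ensemble`.

    One frame per MODEL block (one frame if no MODEL records).  The
    element is taken from columns 77-78 when present, otherwise inferred
    from the atom name.  Raises :class:`ParseError` on inconsistent
    model atom counts (naming the model index) or unparseable
    coordinate fields (naming the line number).
    """
    frames: list[list[tuple]] = []
    current: list[tuple] | None = None
    saw_model = False
    model_index = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            model_index += 1
            if current:
                frames.append(current)
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                frames.append(current)
                current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = []
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = len(current) + 1
            name = line[12:16].strip()
            resname = line[17:21].strip()
            chain = line[21:22].strip() or "A"
            try:
                resid = int(line[22:26])
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: unparseable residue id {line[22:26]!r}"
                ) from exc
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: unparseable coordinate field in {line!r}"
                ) from exc
            element = line[76:78].strip() if len(line) >= 77 else ""
            if not element:
                element = infer_element(name, resname)
            current.append((serial, name, element, resname, resid, chain, x, y, z))
    if current:
        frames.append(current)

    if not frames or not frames[0]:
        raise ParseError("no ATOM/HETATM records found")

    n_atoms = len(frames[0])
    for i, f in enumerate(frames):
        if len(f) != n_atoms:
            raise ParseError(
                f"model {i + 1} has {len(f)} atoms, expected {n_atoms}"
            )

    first = frames[0]
    topology = Structure(
        serial=[a[0] for a in first],
        atom_name=[a[1] for a in first],
        element=[a[2] for a in first],
        residue_name=[a[3] for a in first],
        residue_id=[a[4] for a in first],
        chain_id=[a[5] for a in first],
        coords=[(a[6], a[7], a[8]) for a in first],
    )
    coords = np.array(
        [[(a[6], a[7], a[8]) for a in f] for f in frames], dtype=np.float64
    )
    del saw_model  # frame count alone distinguishes the two layouts
    return Ensemble(topology=topology, coords=coords)


def _pdb_atom_name(name: str, element: str) -> str:
    """PDB column-13-16 atom-name field with conventional justification."""
    if len(name) >= 4:
        return name[:4]
    if len(element.strip()) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(ensemble: Ensemble) -> str:
    """Write an ensemble as fixed-column PDB text.

    Multi-frame ensembles become MODEL/ENDMDL blocks; coordinates are
    rounded to 3 decimals.  Raises :class:`FormatError` when any
    coordinate magnitude does not fit the 8.3f field (≥ 10000 Å).
    """
    if np.any(np.abs(ensemble.coords) >= 10000.0):
        raise FormatError("coordinate magnitude >= 10000 Å does not fit PDB columns")
    top = ensemble.topology
    multi = ensemble.n_frames > 1
    lines: list[str] = []
    for f in range(ensemble.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        xyz = ensemble.coords[f]
        for i in range(top.n_atoms):
            lines.append(
                "ATOM  {serial:5d} {name}{alt}{resname:<4s}{chain}{resid:4d}{icode}   "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}".format(
                    serial=int(top.serial[i]) % 100000,
                    name=_pdb_atom_name(str(top.atom_name[i]), str(top.element[i])),
                    alt=" ",
                    resname=str(top.residue_name[i]),
                    chain=str(top.chain_id[i])[:1],
                    resid=int(top.residue_id[i]) % 10000,
                    icode=" ",
                    x=xyz[i, 0], y=xyz[i, 1], z=xyz[i, 2],
                    occ=1.0, b=0.0,
                    elem=str(top.element[i]).upper()[:2],
                )
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Multi-frame XYZ dialect
# ---------------------------------------------------------------------------

def parse_xyz(text: str) -> Ensemble:
    """Parse the multi-frame XYZ dialect.

    Per frame: a line ``N``, a comment line ``t=<ps>``, then N lines
    ``name resname resid x y z``.  Chain ID is fixed to "A"; elements
    are inferred from atom names.
    """
    lines = text.splitlines()
    pos = 0
    frames: list[np.ndarray] = []
    times: list[float] = []
    meta: list[tuple] | None = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(f"line {pos + 1}: expected atom count") from exc
        comment = lines[pos + 1].strip()
        if not comment.startswith("t="):
            raise ParseError(f"line {pos + 2}: expected comment line 't=<ps>'")
        times.append(float(comment[2:]))
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise ParseError(f"frame starting line {pos + 1}: truncated atom block")
        frame_meta: list[tuple] = []
        xyz = np.empty((n, 3))
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) != 6:
                raise ParseError(
                    f"line {pos + 3 + j}: expected 'name resname resid x y z'"
                )
            name, resname, resid = parts[0], parts[1], int(parts[2])
            xyz[j] = [float(parts[3]), float(parts[4]), float(parts[5])]
            frame_meta.append((name, resname, resid))
        if meta is None:
            meta = frame_meta
        elif frame_meta != meta:
            raise ParseError(
                f"frame {len(frames) + 1}: atom metadata differs from first frame"
            )
        frames.append(xyz)
        pos += 2 + n
    if meta is None:
        raise ParseError("no frames found")
    topology = Structure(
        serial=np.arange(1, len(meta) + 1),
        atom_name=[m[0] for m in meta],
        element=[infer_element(m[0], m[1]) for m in meta],
        residue_name=[m[1] for m in meta],
        residue_id=[m[2] for m in meta],
        chain_id=["A"] * len(meta),
        coords=frames[0],
    )
    return Ensemble(topology=topology, coords=np.array(frames), times=np.array(times))


def write_xyz(ensemble: Ensemble) -> str:
    """Write an ensemble in the multi-frame XYZ dialect."""
    top = ensemble.topology
    times = ensemble.times
    if times is None:
        times = np.arange(ensemble.n_frames, dtype=float)
    out: list[str] = []
    for f in range(ensemble.n_frames):
        out.append(str(top.n_atoms))
        out.append(f"t={times[f]:.6g}")
        for i in range(top.n_atoms):
            x, y, z = ensemble.coords[f, i]
            out.append(
                f"{top.atom_name[i]} {top.residue_name[i]} {int(top.residue_id[i])} "
                f"{x:.6f} {y:.6f} {z:.6f}"
            )
    return "\n".join(out) + "\n"


def read_ensemble(path: str) -> Ensemble:
    """Read a PDB or XYZ-dialect file, dispatching on extension."""
    with open(path) as fh:
        text = fh.read()
    if str(path).lower().endswith((".xyz", ".mfxyz")):
        return parse_xyz(text)
    return parse_structure(text)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def time_window(ensemble: Ensemble, t_start: float, t_end: float) -> Ensemble:
    """Frames with ``t_start <= t < t_end`` (times in ps), order preserved.

    Used to discard equilibration (e.g. the first 50 ns of a replica)
    before clustering or landscape construction.  Raises if the window
    is empty or the ensemble carries no times.
    """
    if ensemble.times is None:
        raise ValueError("ensemble has no times; use frame_window instead")
    if t_start > t_end:
        raise ValueError("t_start must be <= t_end")
    keep = (ensemble.times >= t_start) & (ensemble.times < t_end)
    if not np.any(keep):
        raise ValueError(f"time window [{t_start}, {t_end}) ps keeps no frames")
    return Ensemble(
        topology=ensemble.topology,
        coords=ensemble.coords[keep],
        times=ensemble.times[keep],
    )


def frame_window(ensemble: Ensemble, start: int, stop: int | None = None) -> Ensemble:
    """Frame-index variant of :func:`time_window`: frames ``start <= i < stop``."""
    stop = ensemble.n_frames if stop is None else stop
    if start < 0 or start >= stop:
        raise ValueError("invalid frame window")
    coords = ensemble.coords[start:stop]
    if coords.shape[0] == 0:
        raise ValueError("frame window keeps no frames")
    times = None if ensemble.times is None else ensemble.times[start:stop]
    return Ensemble(topology=ensemble.topology, coords=coords, times=times)
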