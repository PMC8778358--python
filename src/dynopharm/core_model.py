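"""Core domain types and file I/O.

Containers for structures, trajectories and conformer libraries, plus
readers/writers for the plain-text dialects the toolkit exchanges:
fixed-column PDB (ATOM/HETATM/MODEL/ENDMDL/CONECT, with formal charges in
columns 79-80) and SDF V2000 (bond block authoritative, feature points and
scores carried in data fields).

Conventions: coordinates are Angstroms everywhere; atom and bond indices are
0-based internally and converted to 1-based only at the file boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "ConformerRecord",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_sdf",
    "write_sdf",
    "expected_frame_count",
    "infer_bonds",
    "COVALENT_RADII",
    "VDW_RADII",
]

# Covalent radii (Å), Cordero et al. consensus values for common elements.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "NA": 1.66, "K": 2.03,
    "MG": 1.41, "CA": 1.76, "ZN": 1.22, "FE": 1.32, "B": 0.84, "SE": 1.20,
}

# Bondi van der Waals radii (Å) for molecular-volume estimation.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "B": 1.92, "SE": 1.90,
}

_KNOWN_ELEMENTS = set(COVALENT_RADII) | set(VDW_RADII)


@dataclass
class AtomRecord:
    """One atom: identity, residue assignment and Cartesian position (Å)."""

    index: int
    element: str
    name: str
    residue_name: str
    residue_number: int
    chain: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.element = self.element.upper()
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.index}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: non-finite coordinates")
        if self.element not in _KNOWN_ELEMENTS:
            raise ValueError(f"atom {self.index}: unrecognized element {self.element!r}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.residue_name)

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.index, self.element, self.name, self.residue_name,
                          self.residue_number, self.chain, self.coords.copy())


def _canon_bonds(bonds: Iterable[tuple[int, int]]) -> set[tuple[int, int]]:
    out = set()
    for i, j in bonds:
        if i == j:
            raise ValueError(f"self-bond on atom {i}")
        out.add((min(i, j), max(i, j)))
    return out


@dataclass
class Topology:
    """Atoms, connectivity, ligand membership and formal charges.

    ``bonds`` holds unordered 0-based index pairs; ``ligand_selection`` the
    indices of the ligand (everything else is treated as protein).
    """

    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    ligand_selection: set[int] = field(default_factory=set)
    formal_charges: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for a in self.atoms:
            if a.index in seen:
                raise ValueError(f"duplicate atom index {a.index}")
            seen.add(a.index)
        self.bonds = _canon_bonds(self.bonds)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom")
        for i in self.ligand_selection:
            if not (0 <= i < n):
                raise ValueError(f"ligand index {i} out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def protein_indices(self) -> list[int]:
        lig = self.ligand_selection
        return [a.index for a in self.atoms if a.index not in lig]

    def neighbors(self, index: int) -> list[int]:
        return self._adjacency().get(index, [])

    def _adjacency(self) -> dict[int, list[int]]:
        adj = getattr(self, "_adj_cache", None)
        if adj is None or getattr(self, "_adj_nbonds", -1) != len(self.bonds):
            adj: dict[int, list[int]] = {}
            for i, j in sorted(self.bonds):
                adj.setdefault(i, []).append(j)
                adj.setdefault(j, []).append(i)
            self._adj_cache = adj
            self._adj_nbonds = len(self.bonds)
        return adj

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Residue key -> atom indices, in file order."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a.index)
        return out

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def formal_charge(self, index: int) -> int:
        return self.formal_charges.get(index, 0)


@dataclass
class Trajectory:
    """An ordered stack of frames over one topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å. ``frame_spacing`` is the
    saving interval in ps (informational; the production runs this toolkit
    targets save a frame every 10 ps).
    """

    topology: Topology
    frames: np.ndarray
    frame_spacing: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class ConformerRecord:
    """One conformer of a screening-library compound.

    ``feature_points`` may pre-annotate pharmacophore-relevant points as
    (kind, coords) pairs with kind in {HBA, HBD, Aro, Hyd}; when present they
    are used verbatim by the matcher instead of perception.
    """

    name: str
    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    feature_points: list[tuple[str, np.ndarray]] | None = None
    compound: str | None = None
    formal_charges: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bonds = _canon_bonds(self.bonds)
        if self.compound is None:
            self.compound = self.name
        if self.feature_points is not None:
            checked = []
            for kind, xyz in self.feature_points:
                if kind not in ("HBA", "HBD", "Aro", "Hyd"):
                    raise ValueError(f"unknown feature kind {kind!r}")
                xyz = np.asarray(xyz, dtype=float)
                if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                    raise ValueError("feature point coords must be a finite 3-vector")
                checked.append((kind, xyz))
            self.feature_points = checked

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def as_topology(self) -> Topology:
        """View the lone conformer as an all-ligand Topology (for typing rules)."""
        return Topology(atoms=[a.copy() for a in self.atoms], bonds=set(self.bonds),
                        ligand_selection=set(range(len(self.atoms))),
                        formal_charges=dict(self.formal_charges))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int, index: int) -> tuple[AtomRecord, bool, int]:
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip()
        if not element:
            # fall back to the atom-name convention: first alphabetic char
            element = re.sub(r"[^A-Za-z]", "", name)[:1]
        charge = 0
        cfield = line[78:80].strip()
        if cfield:
            m = re.fullmatch(r"(\d)([+-])", cfield) or re.fullmatch(r"([+-])(\d)", cfield[::-1])
            if m is None:
                raise ValueError(f"bad charge field {cfield!r}")
            mag, sign = (cfield[0], cfield[1]) if cfield[0].isdigit() else (cfield[1], cfield[0])
            charge = int(mag) * (1 if sign == "+" else -1)
        atom = AtomRecord(index=index, element=element, name=name,
                          residue_name=resname, residue_number=resnum,
                          chain=chain, coords=np.array([x, y, z]))
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    return atom, line.startswith("HETATM"), charge


def read_structure(path: str | Path, dialect: str = "pdb"):
    """Read a PDB file; return (Topology, first-frame coords ndarray).

    HETATM atoms populate ``ligand_selection``; CONECT records populate bonds
    (serials are remapped to 0-based indices). MODEL blocks beyond the first
    are ignored here — use :func:`read_trajectory` for multi-model files.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    atoms: list[AtomRecord] = []
    ligand: set[int] = set()
    charges: dict[int, int] = {}
    serial_map: dict[int, int] = {}
    bonds: set[tuple[int, int]] = set()
    conect_lines: list[tuple[int, str]] = []
    in_first_model = True
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6]
        if rec == "ENDMDL":
            in_first_model = False
        elif rec in ("ATOM  ", "HETATM"):
            if not in_first_model:
                continue
            idx = len(atoms)
            atom, is_het, charge = _parse_pdb_atom(line, lineno, idx)
            try:
                serial = int(line[6:11])
            except ValueError as exc:
                raise ValueError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
            serial_map[serial] = idx
            atoms.append(atom)
            if is_het:
                ligand.add(idx)
            if charge:
                charges[idx] = charge
        elif rec == "CONECT":
            conect_lines.append((lineno, line))
    if not atoms:
        raise ValueError(f"empty structure: no ATOM/HETATM records in {path}")
    for lineno, line in conect_lines:
        fields = [line[i:i + 5].strip() for i in range(6, min(len(line), 31), 5)]
        serials = [int(f) for f in fields if f]
        if not serials:
            continue
        base = serials[0]
        for other in serials[1:]:
            if base in serial_map and other in serial_map:
                i, j = serial_map[base], serial_map[other]
                if i != j:
                    bonds.add((min(i, j), max(i, j)))
    topo = Topology(atoms=atoms, bonds=bonds, ligand_selection=ligand,
                    formal_charges=charges)
    return topo, topo.coords_array()


def _format_pdb_atom(atom: AtomRecord, serial: int, is_het: bool, charge: int) -> str:
    rec = "HETATM" if is_het else "ATOM  "
    name = atom.name
    # PDB convention: 1-2 char element names start in column 14
    if len(name) < 4:
        name = f" {name:<3s}"
    else:
        name = f"{name:<4s}"
    cfield = ""
    if charge:
        cfield = f"{abs(charge)}{'+' if charge > 0 else '-'}"
    x, y, z = atom.coords
    return (f"{rec}{serial:>5d} {name} {atom.residue_name:>3s} {atom.chain:1s}"
            f"{atom.residue_number:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}{cfield:<2s}")


def _pdb_body(topology: Topology, frame: np.ndarray) -> list[str]:
    lines = []
    for atom in topology.atoms:
        a = atom.copy()
        a.coords = frame[atom.index]
        lines.append(_format_pdb_atom(a, atom.index + 1,
                                      atom.index in topology.ligand_selection,
                                      topology.formal_charge(atom.index)))
    return lines


def _conect_lines(topology: Topology) -> list[str]:
    adj: dict[int, list[int]] = {}
    for i, j in sorted(topology.bonds):
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    lines = []
    for i in sorted(adj):
        partners = sorted(adj[i])
        for k in range(0, len(partners), 4):
            chunk = partners[k:k + 4]
            lines.append("CONECT" + f"{i + 1:>5d}" + "".join(f"{p + 1:>5d}" for p in chunk))
    return lines


def write_structure(path: str | Path, topology: Topology, frame: np.ndarray | None = None) -> None:
    """Write a single-frame PDB (with CONECT records for all bonds)."""
    if frame is None:
        frame = topology.coords_array()
    lines = _pdb_body(topology, np.asarray(frame, dtype=float))
    lines += _conect_lines(topology)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write a multi-model PDB, one MODEL block per frame."""
    lines: list[str] = []
    for f in range(trajectory.n_frames):
        lines.append(f"MODEL {f + 1:>8d}")
        lines += _pdb_body(trajectory.topology, trajectory.frames[f])
        lines.append("ENDMDL")
    lines += _conect_lines(trajectory.topology)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path, topology: Topology,
                    frame_spacing: float = 10.0) -> Trajectory:
    """Read a multi-model PDB as a Trajectory over ``topology``.

    Every MODEL must carry exactly the topology's atom count; a mismatch is an
    error naming the offending model. A file without MODEL records is read as
    a single frame.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    current: list[list[float]] | None = None
    model_index = 0
    saw_model = False

    def close_model():
        nonlocal current
        if current is None:
            return
        if len(current) != topology.n_atoms:
            raise ValueError(
                f"model {model_index} has {len(current)} atoms, expected "
                f"{topology.n_atoms}")
        frames.append(np.array(current, dtype=float))
        current = None

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model = True
            model_index += 1
            current = []
        elif rec == "ENDMDL":
            close_model()
        elif rec in ("ATOM  ", "HETATM"):
            if not saw_model:
                model_index = 1
                current = [] if current is None else current
            if current is None:
                continue  # coordinates outside MODEL blocks after the first
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError as exc:
                raise ValueError(f"malformed coordinates at line {lineno}: {exc}") from exc
            current.append(xyz)
    close_model()
    if not frames:
        raise ValueError(f"no coordinate frames found in {path}")
    return Trajectory(topology=topology, frames=np.array(frames), frame_spacing=frame_spacing)


# ---------------------------------------------------------------------------
# SDF V2000 I/O
# ---------------------------------------------------------------------------

def write_sdf(path: str | Path, conformers: Sequence[ConformerRecord],
              data_fields: Sequence[dict[str, str]] | None = None) -> None:
    """Write conformers as an SDF V2000 multi-record file.

    Feature points are serialized into a ``FEATURES`` data field (one
    ``kind x y z`` line per point); compound names into ``COMPOUND``; formal
    charges into ``M  CHG`` lines. ``data_fields`` optionally adds per-record
    extra fields (e.g. a docking SCORE).
    """
    blocks = []
    for ri, conf in enumerate(conformers):
        lines = [conf.name, "  dynopharm", ""]
        lines.append(f"{len(conf.atoms):>3d}{len(conf.bonds):>3d}  0  0  0  0  0  0  0  0999 V2000")
        for a in conf.atoms:
            x, y, z = a.coords
            sym = a.element.capitalize()
            lines.append(f"{x:>10.4f}{y:>10.4f}{z:>10.4f} {sym:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        for i, j in sorted(conf.bonds):
            lines.append(f"{i + 1:>3d}{j + 1:>3d}  1  0")
        if conf.formal_charges:
            items = sorted(conf.formal_charges.items())
            for k in range(0, len(items), 8):
                chunk = items[k:k + 8]
                lines.append("M  CHG" + f"{len(chunk):>3d}" +
                             "".join(f"{i + 1:>4d}{c:>4d}" for i, c in chunk))
        lines.append("M  END")
        fields: dict[str, str] = {}
        if conf.compound and conf.compound != conf.name:
            fields["COMPOUND"] = conf.compound
        if conf.feature_points is not None:
            fields["FEATURES"] = "\n".join(
                f"{kind} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}" for kind, p in conf.feature_points)
        if data_fields is not None:
            fields.update(data_fields[ri])
        for key, val in fields.items():
            lines.append(f"> <{key}>")
            lines.append(str(val))
            lines.append("")
        lines.append("$$$$")
        blocks.append("\n".join(lines))
    Path(path).write_text("\n".join(blocks) + "\n")


def read_sdf(path: str | Path) -> list[tuple[ConformerRecord, dict[str, str]]]:
    """Read an SDF V2000 file; return [(ConformerRecord, data_fields), ...]."""
    text = Path(path).read_text()
    records = []
    for chunk in text.split("$$$$"):
        lines = chunk.strip("\n").splitlines()
        if not any(l.strip() for l in lines):
            continue
        # strip leading blank lines left by the split
        while lines and not lines[0].strip() and len(lines) > 4:
            lines.pop(0)
        if len(lines) < 4:
            raise ValueError("truncated SDF record")
        name = lines[0].strip()
        counts = lines[3]
        try:
            n_atoms = int(counts[0:3])
            n_bonds = int(counts[3:6])
        except ValueError as exc:
            raise ValueError(f"malformed SDF counts line: {counts!r}") from exc
        atoms: list[AtomRecord] = []
        for i in range(n_atoms):
            al = lines[4 + i]
            x, y, z = float(al[0:10]), float(al[10:20]), float(al[20:30])
            elem = al[30:34].strip()
            atoms.append(AtomRecord(index=i, element=elem, name=f"{elem.upper()}{i + 1}",
                                    residue_name="LIG", residue_number=1, chain="L",
                                    coords=np.array([x, y, z])))
        bonds: set[tuple[int, int]] = set()
        for b in range(n_bonds):
            bl = lines[4 + n_atoms + b]
            i, j = int(bl[0:3]) - 1, int(bl[3:6]) - 1
            bonds.add((min(i, j), max(i, j)))
        charges: dict[int, int] = {}
        cursor = 4 + n_atoms + n_bonds
        while cursor < len(lines) and not lines[cursor].startswith("M  END"):
            ml = lines[cursor]
            if ml.startswith("M  CHG"):
                cnt = int(ml[6:9])
                for k in range(cnt):
                    idx = int(ml[9 + 8 * k:13 + 8 * k]) - 1
                    chg = int(ml[13 + 8 * k:17 + 8 * k])
                    charges[idx] = chg
            cursor += 1
        fields: dict[str, str] = {}
        key = None
        buf: list[str] = []
        for dl in lines[cursor + 1:]:
            m = re.match(r"^>\s*<(.+?)>", dl)
            if m:
                if key is not None:
                    fields[key] = "\n".join(buf).strip("\n")
                key = m.group(1)
                buf = []
            elif key is not None:
                buf.append(dl)
        if key is not None:
            fields[key] = "\n".join(buf).strip("\n")
        feature_points = None
        if "FEATURES" in fields:
            feature_points = []
            for fl in fields["FEATURES"].splitlines():
                if not fl.strip():
                    continue
                kind, xs, ys, zs = fl.split()
                feature_points.append((kind, np.array([float(xs), float(ys), float(zs)])))
        compound = fields.get("COMPOUND", name)
        records.append((ConformerRecord(name=name, atoms=atoms, bonds=bonds,
                                        feature_points=feature_points, compound=compound,
                                        formal_charges=charges), fields))
    return records


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

_TIME_UNITS_PS = {"fs": Fraction(1, 1000), "ps": Fraction(1), "ns": Fraction(1000),
                  "us": Fraction(1_000_000), "µs": Fraction(1_000_000)}


def _to_ps(value) -> Fraction:
    if isinstance(value, str):
        m = re.fullmatch(r"\s*([0-9.]+)\s*([a-zµ]+)\s*", value)
        if not m or m.group(2) not in _TIME_UNITS_PS:
            raise ValueError(f"cannot parse time {value!r}; use e.g. '150 ns' or '10 ps'")
        num = Fraction(m.group(1))
        return num * _TIME_UNITS_PS[m.group(2)]
    return Fraction(str(value))


def expected_frame_count(sim_length, save_interval) -> int:
    """Number of frames saved after every ``save_interval`` of a run.

    Accepts numbers (interpreted as ps) or strings with units ('150 ns',
    '10 ps'). The interval must divide the run length exactly; the t=0
    structure is not counted, so a 150 ns run saved every 10 ps yields 15000
    frames. Exact rational arithmetic throughout.
    """
    length = _to_ps(sim_length)
    interval = _to_ps(save_interval)
    if interval <= 0:
        raise ValueError("save_interval must be positive")
    if length <= 0:
        raise ValueError("sim_length must be positive")
    ratio = length / interval
    if ratio.denominator != 1:
        raise ValueError(f"save interval does not divide simulation length ({ratio})")
    return int(ratio)


def infer_bonds(topology: Topology, scale: float = 1.3,
                indices: Iterable[int] | None = None) -> set[tuple[int, int]]:
    """Infer bonds by the covalent-radii-sum distance rule (opt-in only).

    Two atoms are bonded when their distance < scale * (r_cov_i + r_cov_j).
    Returns the inferred pairs without mutating the topology.
    """
    idx = sorted(indices) if indices is not None else list(range(topology.n_atoms))
    coords = topology.coords_array()
    out: set[tuple[int, int]] = set()
    for a in range(len(idx)):
        i = idx[a]
        ri = COVALENT_RADII.get(topology.atoms[i].element)
        if ri is None:
            raise ValueError(f"no covalent radius for element {topology.atoms[i].element}")
        for b in range(a + 1, len(idx)):
            j = idx[b]
            rj = COVALENT_RADII[topology.atoms[j].element]
            if np.linalg.norm(coords[i] - coords[j]) < scale * (ri + rj):
                out.add((i, j))
    return out
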