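"""Data model for structures, topologies, trajectories and charge sets.

A :class:`Topology` is an ordered list of :class:`AtomRecord` carrying the
per-atom force-field parameters (partial charge, Lennard-Jones rmin/2 and
epsilon, mass, Poisson-Boltzmann radius) plus harmonic bonded terms.
Coordinates travel separately in a :class:`Trajectory` (one or more frames
aligned to the topology's atom order).

File formats
------------
* Structures / trajectories: (multi-model) PDB, parsed and written with
  biotite.  A compact whitespace XYZ dialect is accepted on input only.
* Topology: JSON (full schema, see :func:`write_topology`) or a CSV atoms
  table (bonded terms optional, in sibling ``<stem>_bonds.csv`` /
  ``<stem>_angles.csv`` files).
* Charge sets: two-column CSV ``serial,charge``.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PROTEIN", "LIGAND", "OTHER",
    "AtomRecord", "Bond", "Angle", "Topology", "Trajectory", "ChargeSet",
    "Selection", "TopologyError", "SelectionError", "StructureParseError",
    "read_structure", "write_structure", "read_topology", "write_topology",
    "read_charge_set", "write_charge_set", "apply_charge_set", "select",
]

PROTEIN = "protein"
LIGAND = "ligand"
OTHER = "other"

_WATER_NAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O", "SPC"}
_ION_NAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "BR", "F", "LI", "CS", "IOD",
              "NA+", "CL-", "K+", "MG2", "CAL"}

# fallback per-element defaults for PDB-skeleton topologies
_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "S": 32.06, "P": 30.974, "F": 18.998, "CL": 35.45,
                 "BR": 79.904, "NA": 22.990, "K": 39.098, "MG": 24.305}
_ELEMENT_PB_RADIUS = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
                      "S": 1.80, "P": 1.80, "F": 1.47, "CL": 1.75}


class TopologyError(ValueError):
    """Topology schema or invariant violation."""


class SelectionError(ValueError):
    """Bad selection expression or out-of-range indices."""


class StructureParseError(ValueError):
    """Malformed structure file."""


@dataclass
class AtomRecord:
    """One atom with coordinates and force-field parameters.

    ``position`` is the reference (native) position in Angstrom; trajectory
    frames supply alternatives.  ``lj_rmin_half`` / ``lj_epsilon`` are the
    AMBER-style Lennard-Jones parameters (rmin/2 in A, well depth in
    kcal/mol); ``pb_radius`` is the dielectric-boundary radius in A.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    segment: str = PROTEIN
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    charge: float = 0.0
    lj_rmin_half: float = 1.5
    lj_epsilon: float = 0.0
    mass: float = 12.0
    pb_radius: float = 1.5

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.pb_radius <= 0:
            raise TopologyError(f"atom {self.serial}: pb_radius must be > 0")
        if self.lj_epsilon < 0:
            raise TopologyError(f"atom {self.serial}: lj_epsilon must be >= 0")
        if self.mass <= 0:
            raise TopologyError(f"atom {self.serial}: mass must be > 0")
        if self.segment not in (PROTEIN, LIGAND, OTHER):
            raise TopologyError(f"atom {self.serial}: bad segment {self.segment!r}")


@dataclass(frozen=True)
class Bond:
    """Harmonic bond i-j: E = k (r - r0)^2, k in kcal/mol/A^2, r0 in A."""
    i: int
    j: int
    k: float
    r0: float


@dataclass(frozen=True)
class Angle:
    """Harmonic angle i-j-k: E = k (theta - theta0)^2, theta in rad."""
    i: int
    j: int
    k: int
    force_k: float
    theta0: float


class Topology:
    """Ordered atoms plus harmonic bonded terms.

    Parameters are validated on construction: indices in range, each
    unordered bond pair stored once, per-atom invariants via
    :class:`AtomRecord`.
    """

    def __init__(self, atoms, bonds=(), angles=()):
        self.atoms: list[AtomRecord] = list(atoms)
        self.bonds: list[Bond] = [b if isinstance(b, Bond) else Bond(*b) for b in bonds]
        self.angles: list[Angle] = [a if isinstance(a, Angle) else Angle(*a) for a in angles]
        self._validate()
        self._cache: dict = {}

    # -- validation ---------------------------------------------------
    def _validate(self):
        n = len(self.atoms)
        if n == 0:
            raise TopologyError("topology has zero atoms")
        seen_pairs = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise TopologyError(f"bond ({b.i},{b.j}) index out of range")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen_pairs:
                raise TopologyError(f"bond pair {key} stored more than once")
            seen_pairs.add(key)
        for a in self.angles:
            if not all(0 <= x < n for x in (a.i, a.j, a.k)):
                raise TopologyError(f"angle ({a.i},{a.j},{a.k}) index out of range")
        # residue_index non-decreasing within a segment block
        prev_seg, prev_idx = None, None
        for at in self.atoms:
            if at.segment == prev_seg and at.residue_index < prev_idx:
                raise TopologyError(
                    f"residue_index decreases at atom serial {at.serial}")
            prev_seg, prev_idx = at.segment, at.residue_index

    # -- array views --------------------------------------------------
    def _arr(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return self._arr("pos", lambda: np.array([a.position for a in self.atoms]))

    @property
    def charges(self) -> np.ndarray:
        return self._arr("q", lambda: np.array([a.charge for a in self.atoms]))

    @property
    def masses(self) -> np.ndarray:
        return self._arr("m", lambda: np.array([a.mass for a in self.atoms]))

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return self._arr("rmh", lambda: np.array([a.lj_rmin_half for a in self.atoms]))

    @property
    def lj_epsilon(self) -> np.ndarray:
        return self._arr("eps", lambda: np.array([a.lj_epsilon for a in self.atoms]))

    @property
    def pb_radii(self) -> np.ndarray:
        return self._arr("pbr", lambda: np.array([a.pb_radius for a in self.atoms]))

    @property
    def residue_indices(self) -> np.ndarray:
        return self._arr("rid", lambda: np.array([a.residue_index for a in self.atoms]))

    @property
    def names(self) -> np.ndarray:
        return self._arr("nm", lambda: np.array([a.name for a in self.atoms]))

    @property
    def segments(self) -> np.ndarray:
        return self._arr("seg", lambda: np.array([a.segment for a in self.atoms]))

    @property
    def elements(self) -> np.ndarray:
        return self._arr("el", lambda: np.array([a.element for a in self.atoms]))

    @property
    def residues(self) -> pd.DataFrame:
        """Table of (name, index, segment, start, stop) atom spans."""
        def build():
            rows = []
            start = 0
            for i in range(1, self.n_atoms + 1):
                boundary = i == self.n_atoms or (
                    (self.atoms[i].residue_index, self.atoms[i].segment)
                    != (self.atoms[start].residue_index, self.atoms[start].segment))
                if boundary:
                    a0 = self.atoms[start]
                    rows.append((a0.residue_name, a0.residue_index, a0.segment,
                                 start, i))
                    start = i
            return pd.DataFrame(rows, columns=["name", "index", "segment",
                                               "start", "stop"])
        return self._arr("res", build)

    def bonded_neighbors(self) -> list[set]:
        """Adjacency sets from the bond list."""
        def build():
            adj = [set() for _ in range(self.n_atoms)]
            for b in self.bonds:
                adj[b.i].add(b.j)
                adj[b.j].add(b.i)
            return adj
        return self._arr("adj", build)

    def exclusion_pairs(self) -> set:
        """1-2 and 1-3 pairs (as sorted tuples) excluded from nonbonded terms."""
        def build():
            adj = self.bonded_neighbors()
            excl = set()
            for b in self.bonds:
                excl.add((min(b.i, b.j), max(b.i, b.j)))
            for j, nbrs in enumerate(adj):
                for i in nbrs:
                    for k in nbrs:
                        if i < k:
                            excl.add((i, k))
            return excl
        return self._arr("excl", build)

    def with_positions(self, coords) -> "Topology":
        coords = np.asarray(coords, float)
        atoms = [dataclasses.replace(a, position=coords[i])
                 for i, a in enumerate(self.atoms)]
        return Topology(atoms, self.bonds, self.angles)


@dataclass
class Trajectory:
    """Ordered coordinate frames aligned to a topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``frame_index``
    is strictly increasing; ``times`` is in ns.
    """

    topology: Topology
    coords: np.ndarray
    frame_index: np.ndarray = None
    times: np.ndarray = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frame atom count {self.coords.shape[1]} != topology "
                f"{self.topology.n_atoms}")
        if self.frame_index is None:
            self.frame_index = np.arange(1, len(self.coords) + 1)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if np.any(np.diff(self.frame_index) <= 0):
            raise TopologyError("frame_index must be strictly increasing")
        if self.times is None:
            self.times = np.asarray(self.frame_index, dtype=float)
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def subset(self, frame_positions) -> "Trajectory":
        """New trajectory from frame positions (0-based into this one)."""
        idx = np.asarray(frame_positions, dtype=int)
        return Trajectory(self.topology, self.coords[idx],
                          self.frame_index[idx], self.times[idx])


@dataclass
class ChargeSet:
    """A named per-atom partial-charge vector (e).

    The total charge must be within 1e-3 e of an integer (fragment charges
    are integers; fitted charges carry rounding).
    """

    label: str
    charges: np.ndarray

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        total = float(self.charges.sum())
        if abs(total - round(total)) > 1e-3:
            raise TopologyError(
                f"charge set {self.label!r}: total {total:.4f} e is not "
                "within 1e-3 of an integer")

    def __len__(self):
        return len(self.charges)


@dataclass(frozen=True)
class Selection:
    """An atom index set with the expression that produced it."""

    indices: tuple
    provenance: str = ""

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise SelectionError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    @property
    def index_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)

    def __len__(self):
        return len(self.indices)


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def _segment_for(res_name: str, hetero: bool) -> str:
    rn = res_name.strip().upper()
    if rn in _WATER_NAMES or rn in _ION_NAMES:
        return OTHER
    return LIGAND if hetero else PROTEIN


def _check_pdb_coordinates(path):
    """Pre-scan ATOM/HETATM records so coordinate errors carry line numbers."""
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n_atoms += 1
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fragment = line[lo:hi]
                    try:
                        float(fragment)
                    except ValueError:
                        raise StructureParseError(
                            f"{path}: line {lineno}: malformed {what} "
                            f"coordinate field {fragment!r}") from None
    if n_atoms == 0:
        raise StructureParseError(f"{path}: no ATOM/HETATM records")


def read_structure(path, dialect="pdb"):
    """Read a structure file into a skeleton topology plus trajectory.

    One trajectory frame per MODEL record (a single frame if there are
    none).  HETATM atoms become segment ``ligand`` unless they are waters or
    monatomic ions (segment ``other``).  Charges/LJ/mass/PB-radius fields of
    the skeleton are element-based defaults; load a real topology with
    :func:`read_topology` for energetics.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "xyz":
        return _read_xyz(path)
    if dialect != "pdb":
        raise ValueError(f"unknown dialect {dialect!r}")

    _check_pdb_coordinates(path)
    from biotite.structure.io.pdb import PDBFile
    stack = PDBFile.read(str(path)).get_structure(model=None)

    hetero = stack.hetero
    atoms = []
    for i in range(stack.array_length()):
        element = str(stack.element[i]).upper() or "C"
        atoms.append(AtomRecord(
            serial=i + 1,
            name=str(stack.atom_name[i]),
            element=element,
            residue_name=str(stack.res_name[i]),
            residue_index=int(stack.res_id[i]),
            segment=_segment_for(str(stack.res_name[i]), bool(hetero[i])),
            position=stack.coord[0, i],
            mass=_ELEMENT_MASS.get(element, 12.0),
            pb_radius=_ELEMENT_PB_RADIUS.get(element, 1.5),
        ))
    topology = Topology(atoms)
    traj = Trajectory(topology, np.array(stack.coord))
    return topology, traj


def _read_xyz(path):
    """Whitespace XYZ: repeated blocks of 'N / comment / name x y z'."""
    frames, names = [], None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError:
            raise StructureParseError(
                f"{path}: line {pos + 1}: expected atom count") from None
        block = lines[pos + 2:pos + 2 + n]
        if len(block) < n:
            raise StructureParseError(f"{path}: truncated frame at line {pos + 1}")
        frame_names, coords = [], []
        for off, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise StructureParseError(
                    f"{path}: line {pos + 3 + off}: expected 'name x y z'")
            frame_names.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:4]])
            except ValueError:
                raise StructureParseError(
                    f"{path}: line {pos + 3 + off}: malformed coordinate") from None
        if names is None:
            names = frame_names
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise StructureParseError(f"{path}: no frames")
    atoms = [AtomRecord(serial=i + 1, name=nm, element=nm[:1].upper(),
                        residue_name="UNK", residue_index=1,
                        position=frames[0][i],
                        mass=_ELEMENT_MASS.get(nm[:1].upper(), 12.0),
                        pb_radius=_ELEMENT_PB_RADIUS.get(nm[:1].upper(), 1.5))
             for i, nm in enumerate(names)]
    topology = Topology(atoms)
    return topology, Trajectory(topology, np.array(frames))


def write_structure(path, topology, trajectory=None, coords=None):
    """Write a (multi-model) PDB.  Fixed-width, 3-decimal coordinates."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if trajectory is not None:
        frames = trajectory.coords
    elif coords is not None:
        frames = np.asarray(coords, float)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        frames = topology.positions[None]

    n = topology.n_atoms
    stack = struc.AtomArrayStack(len(frames), n)
    stack.coord = np.asarray(frames, float)
    chain_for = {PROTEIN: "A", LIGAND: "L", OTHER: "X"}
    stack.set_annotation("chain_id", np.array(
        [chain_for[a.segment] for a in topology.atoms], dtype="U4"))
    stack.set_annotation("res_id", np.array(
        [a.residue_index for a in topology.atoms]))
    stack.set_annotation("res_name", np.array(
        [a.residue_name for a in topology.atoms], dtype="U5"))
    stack.set_annotation("atom_name", np.array(
        [a.name for a in topology.atoms], dtype="U6"))
    stack.set_annotation("element", np.array(
        [a.element for a in topology.atoms], dtype="U2"))
    stack.set_annotation("hetero", np.array(
        [a.segment != PROTEIN for a in topology.atoms]))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# topology I/O
# ---------------------------------------------------------------------------

_ATOM_COLUMNS = ["serial", "name", "element", "residue_name", "residue_index",
                 "segment", "x", "y", "z", "charge", "lj_rmin_half",
                 "lj_epsilon", "mass", "pb_radius"]


def _atom_from_row(row):
    return AtomRecord(
        serial=int(row["serial"]), name=str(row["name"]),
        element=str(row["element"]), residue_name=str(row["residue_name"]),
        residue_index=int(row["residue_index"]), segment=str(row["segment"]),
        position=np.array([row["x"], row["y"], row["z"]], float),
        charge=float(row["charge"]), lj_rmin_half=float(row["lj_rmin_half"]),
        lj_epsilon=float(row["lj_epsilon"]), mass=float(row["mass"]),
        pb_radius=float(row["pb_radius"]))


def read_topology(path):
    """Load a topology from JSON (full) or CSV (atoms table) dialects.

    The CSV dialect reads bonded terms from optional sibling files
    ``<stem>_bonds.csv`` (i,j,k,r0) and ``<stem>_angles.csv``
    (i,j,k,force_k,theta0).
    """
    path = pathlib.Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("atoms",):
            if key not in data:
                raise TopologyError(f"{path}: missing {key!r} section")
        atoms_df = pd.DataFrame(data["atoms"])
        missing = set(_ATOM_COLUMNS) - set(atoms_df.columns)
        if missing:
            raise TopologyError(f"{path}: missing atom columns {sorted(missing)}")
        atoms = [_atom_from_row(r) for _, r in atoms_df.iterrows()]
        bonds = [Bond(int(b[0]), int(b[1]), float(b[2]), float(b[3]))
                 for b in data.get("bonds", [])]
        angles = [Angle(int(a[0]), int(a[1]), int(a[2]), float(a[3]), float(a[4]))
                  for a in data.get("angles", [])]
        return Topology(atoms, bonds, angles)
    if path.suffix.lower() == ".csv":
        atoms_df = pd.read_csv(path)
        missing = set(_ATOM_COLUMNS) - set(atoms_df.columns)
        if missing:
            raise TopologyError(f"{path}: missing atom columns {sorted(missing)}")
        atoms = [_atom_from_row(r) for _, r in atoms_df.iterrows()]
        bonds, angles = [], []
        bpath = path.with_name(path.stem + "_bonds.csv")
        if bpath.exists():
            for _, r in pd.read_csv(bpath).iterrows():
                bonds.append(Bond(int(r["i"]), int(r["j"]),
                                  float(r["k"]), float(r["r0"])))
        apath = path.with_name(path.stem + "_angles.csv")
        if apath.exists():
            for _, r in pd.read_csv(apath).iterrows():
                angles.append(Angle(int(r["i"]), int(r["j"]), int(r["k"]),
                                    float(r["force_k"]), float(r["theta0"])))
        return Topology(atoms, bonds, angles)
    raise TopologyError(f"{path}: unknown topology dialect {path.suffix!r}")


def write_topology(path, topology):
    """Write JSON (``.json``) or CSV (``.csv`` + bonded siblings)."""
    path = pathlib.Path(path)
    rows = [{
        "serial": a.serial, "name": a.name, "element": a.element,
        "residue_name": a.residue_name, "residue_index": a.residue_index,
        "segment": a.segment, "x": float(a.position[0]),
        "y": float(a.position[1]), "z": float(a.position[2]),
        "charge": a.charge, "lj_rmin_half": a.lj_rmin_half,
        "lj_epsilon": a.lj_epsilon, "mass": a.mass, "pb_radius": a.pb_radius,
    } for a in topology.atoms]
    if path.suffix.lower() == ".json":
        data = {
            "atoms": rows,
            "bonds": [[b.i, b.j, b.k, b.r0] for b in topology.bonds],
            "angles": [[a.i, a.j, a.k, a.force_k, a.theta0]
                       for a in topology.angles],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
        return
    if path.suffix.lower() == ".csv":
        pd.DataFrame(rows, columns=_ATOM_COLUMNS).to_csv(path, index=False)
        if topology.bonds:
            pd.DataFrame([(b.i, b.j, b.k, b.r0) for b in topology.bonds],
                         columns=["i", "j", "k", "r0"]).to_csv(
                path.with_name(path.stem + "_bonds.csv"), index=False)
        if topology.angles:
            pd.DataFrame([(a.i, a.j, a.k, a.force_k, a.theta0)
                          for a in topology.angles],
                         columns=["i", "j", "k", "force_k", "theta0"]).to_csv(
                path.with_name(path.stem + "_angles.csv"), index=False)
        return
    raise TopologyError(f"{path}: unknown topology dialect {path.suffix!r}")


def read_charge_set(path, label=None):
    """Read a two-column (serial, charge) CSV into a :class:`ChargeSet`."""
    df = pd.read_csv(path)
    if not {"serial", "charge"} <= set(df.columns):
        raise TopologyError(f"{path}: charge set needs serial,charge columns")
    df = df.sort_values("serial")
    return ChargeSet(label or pathlib.Path(path).stem,
                     df["charge"].to_numpy(float))


def write_charge_set(path, charge_set):
    pd.DataFrame({"serial": np.arange(1, len(charge_set) + 1),
                  "charge": charge_set.charges}).to_csv(path, index=False)


def apply_charge_set(topology: Topology, cs: ChargeSet) -> Topology:
    """Return a topology identical to the input except for atomic charges."""
    if len(cs) != topology.n_atoms:
        raise TopologyError(
            f"charge set {cs.label!r} has {len(cs)} charges for "
            f"{topology.n_atoms} atoms")
    atoms = [dataclasses.replace(a, charge=float(cs.charges[i]))
             for i, a in enumerate(topology.atoms)]
    return Topology(atoms, topology.bonds, topology.angles)


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------
# grammar:  expr   := term ('or' term)*
#           term   := factor ('and' factor)*
#           factor := 'not' factor | '(' expr ')' | primitive
# primitives: all | none | backbone | calpha/ca | protein | ligand | other
#             | segment NAME | name N1 N2 ... | resname R1 R2 ...
#             | resid SPEC...   (SPEC = int or lo:hi inclusive)

_BACKBONE_NAMES = {"N", "CA", "C", "O"}
_KEYWORDS = {"and", "or", "not", "(", ")", "all", "none", "backbone",
             "calpha", "ca", "protein", "ligand", "other", "segment",
             "name", "resname", "resid"}


def _tokenize(expr):
    out = []
    for raw in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _SelParser:
    def __init__(self, tokens, topology):
        self.toks = tokens
        self.pos = 0
        self.top = topology

    def peek(self):
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self):
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self):
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression")
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primitive()

    def _values(self):
        vals = []
        stop = {"and", "or", "not", "(", ")"}
        while self.peek() is not None and self.peek().lower() not in stop:
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword needs at least one value")
        return vals

    def primitive(self):
        top = self.top
        tok = self.take().lower()
        if tok == "all":
            return np.ones(top.n_atoms, bool)
        if tok == "none":
            return np.zeros(top.n_atoms, bool)
        if tok == "backbone":
            return np.isin(top.names, list(_BACKBONE_NAMES)) & (
                top.segments == PROTEIN)
        if tok in ("calpha", "ca"):
            return (top.names == "CA") & (top.segments == PROTEIN)
        if tok in (PROTEIN, LIGAND, OTHER):
            return top.segments == tok
        if tok == "segment":
            return np.isin(top.segments, [v.lower() for v in self._values()])
        if tok == "name":
            return np.isin(top.names, [v.upper() for v in self._values()])
        if tok == "resname":
            rn = np.array([a.residue_name for a in top.atoms])
            return np.isin(rn, [v.upper() for v in self._values()])
        if tok == "resid":
            mask = np.zeros(top.n_atoms, bool)
            rid = top.residue_indices
            for v in self._values():
                if ":" in v:
                    lo, hi = v.split(":")
                    try:
                        mask |= (rid >= int(lo)) & (rid <= int(hi))
                    except ValueError:
                        raise SelectionError(f"bad resid range {v!r}") from None
                else:
                    try:
                        mask |= rid == int(v)
                    except ValueError:
                        raise SelectionError(f"bad resid {v!r}") from None
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select(topology: Topology, expr: str) -> Selection:
    """Evaluate a selection expression against a topology.

    Examples: ``"backbone"``, ``"resid 214 and name O"``,
    ``"segment ligand"``, ``"resid 3:10 and not name H"``.
    """
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelParser(tokens, topology).parse()
    return Selection(tuple(np.nonzero(mask)[0].tolist()), provenance=expr)
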