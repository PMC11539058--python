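"""Trajectory and tabular I/O with the package's coordinate and unit conventions.

Conventions used throughout the package:

* coordinates in Angstrom, times in nanoseconds;
* default frame spacing 0.1 ns when a file carries no time information;
* residues numbered continuously across chains (for a Fab fragment, light
  chain 1-214 followed by heavy chain 215-442) so that heavy-chain
  aggregation-prone regions such as 387-402 live on a single index;
* ranges in user-facing APIs are 1-based and inclusive; internal array
  indices are 0-based.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Trajectory",
    "FormulationCondition",
    "ConditionTable",
    "TrajectoryFormatError",
    "ConditionTableError",
    "read_structure",
    "write_trajectory",
    "read_condition_table",
    "write_bfactor_map",
    "ELEMENT_MASSES",
    "VDW_RADII",
]

#: Atomic masses in Da for the elements that occur in protein models.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
}

#: Default van der Waals radii in Angstrom (overridable via config).
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
    "SE": 1.90, "FE": 1.80, "ZN": 1.39,
}

DEFAULT_FRAME_SPACING_NS = 0.1


class TrajectoryFormatError(ValueError):
    """Raised when a structure/trajectory file violates the expected dialect."""


class ConditionTableError(ValueError):
    """Raised when a formulation-condition table fails validation."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``residue_index`` is the continuous 1-based index over all chains.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    mass: float
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.serial < 1:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if self.residue_index < 1:
            raise ValueError(
                f"residue_index must be >= 1, got {self.residue_index}"
            )
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be > 0")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")
        if self.element not in ELEMENT_MASSES:
            raise ValueError(
                f"atom {self.serial}: unknown element {self.element!r}"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Trajectory:
    """An ordered topology plus one or more coordinate frames.

    Attributes
    ----------
    topology : list of AtomRecord
    coordinates : ndarray, shape (n_frames, n_atoms, 3), Angstrom
    times : ndarray, shape (n_frames,), nanoseconds, strictly increasing
    """

    topology: list[AtomRecord]
    coordinates: np.ndarray
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim == 2:
            self.coordinates = self.coordinates[None, :, :]
        if self.times is None:
            self.times = DEFAULT_FRAME_SPACING_NS * np.arange(
                self.coordinates.shape[0]
            )
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != len(self.topology):
            raise ValueError(
                f"coordinate frames carry {self.coordinates.shape[1]} atoms "
                f"but the topology has {len(self.topology)}"
            )
        if self.coordinates.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if len(self.times) != self.coordinates.shape[0]:
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.topology])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.topology])

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.topology])

    def atom_indices(self, *, element: str | None = None,
                     name: str | None = None,
                     heavy_only: bool = False) -> np.ndarray:
        """0-based indices of atoms matching the given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if element is not None:
            mask &= self.elements == element
        if name is not None:
            mask &= np.array([a.name == name for a in self.topology])
        if heavy_only:
            mask &= self.elements != "H"
        return np.nonzero(mask)[0]


@dataclass(frozen=True)
class FormulationCondition:
    """One solution environment of the formulation study.

    ``tm`` is stored exactly as printed in the source table.  Its header
    claims Kelvin but the values (59.5-83.2) are evidently degrees Celsius,
    so the field is treated as "degrees as printed" and never converted.
    """

    condition_id: int
    temperature: float          # K
    ionic_strength: float       # mM NaCl
    pH: float
    tm: float                   # degrees_as_printed (melting temperature)
    ln_v: float                 # ln of aggregation rate, v in % day^-1

    VALID_TEMPERATURES = (277.0, 296.0, 318.0, 338.0)
    VALID_PHS = (3.5, 4.5, 5.5, 7.0, 8.0, 9.0)

    def __post_init__(self) -> None:
        if not 1 <= self.condition_id <= 49:
            raise ValueError(f"condition_id must be 1-49, got {self.condition_id}")
        if self.temperature not in self.VALID_TEMPERATURES:
            raise ValueError(
                f"condition {self.condition_id}: temperature {self.temperature} "
                f"not in {self.VALID_TEMPERATURES}"
            )
        if self.ionic_strength < 0:
            raise ValueError(
                f"condition {self.condition_id}: ionic strength must be >= 0"
            )
        if self.pH not in self.VALID_PHS:
            raise ValueError(
                f"condition {self.condition_id}: pH {self.pH} not in {self.VALID_PHS}"
            )


class ConditionTable:
    """The 49-condition formulation table as validated records + DataFrame."""

    COLUMNS = ["number", "temperature", "ionic_strength", "pH", "tm", "ln_v"]

    def __init__(self, conditions: list[FormulationCondition]):
        if not conditions:
            raise ConditionTableError("no data rows")
        self.conditions = list(conditions)

    def __len__(self) -> int:
        return len(self.conditions)

    def __getitem__(self, i: int) -> FormulationCondition:
        return self.conditions[i]

    def by_id(self, condition_id: int) -> FormulationCondition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "number": [c.condition_id for c in self.conditions],
                "temperature": [c.temperature for c in self.conditions],
                "ionic_strength": [c.ionic_strength for c in self.conditions],
                "pH": [c.pH for c in self.conditions],
                "tm": [c.tm for c in self.conditions],
                "ln_v": [c.ln_v for c in self.conditions],
            }
        ).set_index("number")


# ---------------------------------------------------------------------------
# element inference

_TWO_LETTER = {"SE", "FE", "ZN", "CL", "BR", "NA", "MG", "CA"}


def infer_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Strips digits and primes, then prefers a known two-letter symbol and
    falls back to the first alphabetic character.
    """
    stripped = "".join(ch for ch in atom_name if ch.isalpha()).upper()
    if not stripped:
        raise TrajectoryFormatError(f"cannot infer element from name {atom_name!r}")
    if stripped[:2] in _TWO_LETTER and stripped[:2] in ELEMENT_MASSES:
        return stripped[:2]
    return stripped[0]


def _make_record(serial: int, name: str, element: str, res_name: str,
                 res_index: int, chain_id: str,
                 vdw_overrides: dict[str, float] | None = None) -> AtomRecord:
    element = element.strip().upper()
    if not element:
        element = infer_element(name)
    if element not in ELEMENT_MASSES:
        raise TrajectoryFormatError(
            f"unknown element {element!r} for atom serial {serial}"
        )
    radii = dict(VDW_RADII)
    if vdw_overrides:
        radii.update(vdw_overrides)
    if element not in radii:
        raise TrajectoryFormatError(
            f"no van der Waals radius for element {element!r} (atom {serial})"
        )
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=res_name,
        residue_index=res_index, chain_id=chain_id,
        mass=ELEMENT_MASSES[element], vdw_radius=radii[element],
    )


# ---------------------------------------------------------------------------
# PDB

def _prescan_pdb_models(text: str) -> list[int]:
    """Atom counts per MODEL block (single implicit model if none declared)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for line in text.splitlines():
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model = True
            in_model = True
            current = 0
        elif rec.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif rec.startswith(("ATOM  ", "HETATM")):
            current += 1
            if not saw_model:
                in_model = True
    if in_model and (not saw_model or current):
        if not saw_model:
            counts.append(current)
    return counts


def _read_pdb(path: Path, vdw_overrides: dict[str, float] | None) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    text = Path(path).read_text()
    counts = _prescan_pdb_models(text)
    if not counts or all(c == 0 for c in counts):
        raise TrajectoryFormatError(f"{path}: no ATOM records found")
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise TrajectoryFormatError(
            f"{path}: model {bad} has {counts[bad - 1]} atoms, "
            f"expected {counts[0]} (all models must share the atom list)"
        )

    pdb = PDBFile.read(io.StringIO(text))
    stack = pdb.get_structure(model=None)  # AtomArrayStack
    coords = np.asarray(stack.coord, dtype=float)

    # continuous residue numbering in order of first appearance
    res_index_map: dict[tuple[str, int, str], int] = {}
    topology: list[AtomRecord] = []
    for i in range(stack.array_length()):
        key = (str(stack.chain_id[i]), int(stack.res_id[i]),
               str(stack.ins_code[i]) if hasattr(stack, "ins_code") else "")
        if key not in res_index_map:
            res_index_map[key] = len(res_index_map) + 1
        topology.append(
            _make_record(
                serial=i + 1,
                name=str(stack.atom_name[i]),
                element=str(stack.element[i]),
                res_name=str(stack.res_name[i]),
                res_index=res_index_map[key],
                chain_id=str(stack.chain_id[i]) or "A",
                vdw_overrides=vdw_overrides,
            )
        )
    return Trajectory(topology=topology, coordinates=coords)


def _write_pdb(traj: Trajectory, path: Path,
               bfactors: np.ndarray | None = None) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_atoms
    template = struc.AtomArray(n)
    template.coord = traj.coordinates[0].astype(np.float32)
    template.chain_id = np.array([a.chain_id for a in traj.topology])
    template.res_id = np.array([a.residue_index for a in traj.topology])
    template.res_name = np.array([a.residue_name for a in traj.topology])
    template.atom_name = np.array([a.name for a in traj.topology])
    template.element = np.array([a.element for a in traj.topology])
    template.set_annotation(
        "b_factor",
        np.zeros(n) if bfactors is None else np.asarray(bfactors, dtype=float),
    )
    pdb = PDBFile()
    if traj.n_frames == 1:
        pdb.set_structure(template)
    else:
        stack = struc.stack([template] * traj.n_frames)
        stack.coord = traj.coordinates.astype(np.float32)
        pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# extended XYZ (comment line carries the frame time in ns)

def _write_xyz(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"time={traj.times[f]:.6f} ns\n")
            for a, (x, y, z) in zip(traj.topology, traj.coordinates[f]):
                fh.write(f"{a.element:<2s} {x:15.6f} {y:15.6f} {z:15.6f}\n")


def _read_xyz(path: Path, vdw_overrides: dict[str, float] | None) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    times: list[float] = []
    elements: list[str] | None = None
    i = 0
    model = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        model += 1
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: expected atom count at line {i + 1}"
            ) from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = None
        if "time=" in comment:
            try:
                t = float(comment.split("time=")[1].split()[0])
            except (IndexError, ValueError):
                t = None
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise TrajectoryFormatError(
                f"{path}: frame {model} truncated ({len(block)} of {n} atoms)"
            )
        els = [ln.split()[0] for ln in block]
        if elements is None:
            elements = els
        elif els != elements:
            raise TrajectoryFormatError(
                f"{path}: model {model} atom list differs from model 1"
            )
        frames.append(
            np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        )
        times.append(t if t is not None else DEFAULT_FRAME_SPACING_NS * (model - 1))
        i += 2 + n
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    topology = [
        _make_record(serial=j + 1, name=el, element=el, res_name="UNK",
                     res_index=j + 1, chain_id="A",
                     vdw_overrides=vdw_overrides)
        for j, el in enumerate(elements or [])
    ]
    return Trajectory(topology=topology, coordinates=np.array(frames),
                      times=np.array(times))


# ---------------------------------------------------------------------------
# public API

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    if suffix == ".pdb":
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    raise TrajectoryFormatError(
        f"cannot infer format from {path}; pass format='pdb' or 'xyz'"
    )


def read_structure(path, format: str | None = None,
                   vdw_overrides: dict[str, float] | None = None) -> Trajectory:
    """Read a (multi-model) PDB or extended-XYZ file into a :class:`Trajectory`.

    Elements are taken from the file when present and inferred from atom
    names otherwise; masses and van der Waals radii come from the built-in
    element table.  Frame times default to 0.1 ns spacing when the file
    carries none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        return _read_pdb(path, vdw_overrides)
    if fmt == "xyz":
        return _read_xyz(path, vdw_overrides)
    raise TrajectoryFormatError(f"unsupported format {fmt!r}")


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or extended XYZ."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _write_pdb(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    else:
        raise TrajectoryFormatError(f"unsupported format {fmt!r}")


def read_condition_table(path) -> ConditionTable:
    """Read and validate a formulation-condition CSV.

    The CSV must carry the header columns
    ``number,temperature,ionic_strength,pH,tm,ln_v``.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ConditionTableError("no data rows") from exc
    missing = set(ConditionTable.COLUMNS) - set(df.columns)
    if missing:
        raise ConditionTableError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise ConditionTableError("no data rows")
    conditions = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            conditions.append(
                FormulationCondition(
                    condition_id=int(row.number),
                    temperature=float(row.temperature),
                    ionic_strength=float(row.ionic_strength),
                    pH=float(row.pH),
                    tm=float(row.tm),
                    ln_v=float(row.ln_v),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ConditionTableError(f"row {row_no}: {exc}") from exc
    return ConditionTable(conditions)


def write_bfactor_map(reference: Trajectory, per_residue_values, path) -> None:
    """Write a single-model PDB whose B-factor column carries a per-residue value.

    Used to colour a structure by residue-level statistics (e.g. the
    squared correlation between per-residue fluctuation and aggregation
    rate).  Values are clipped to [0, 99.99], the PDB column's range at two
    decimals; clipping emits a warning.
    """
    values = dict(per_residue_values)
    res_ids = sorted({a.residue_index for a in reference.topology})
    missing = [r for r in res_ids if r not in values]
    if missing:
        raise ValueError(f"no value for residue indices: {missing}")
    raw = np.array([values[a.residue_index] for a in reference.topology],
                   dtype=float)
    clipped = np.clip(raw, 0.0, 99.99)
    if np.any(raw != clipped):
        n_clip = int(np.sum(raw != clipped))
        warnings.warn(
            f"{n_clip} B-factor value(s) clipped to [0, 99.99]",
            stacklevel=2,
        )
        logger.warning("clipped %d B-factor values to [0, 99.99]", n_clip)
    ref_frame = Trajectory(
        topology=reference.topology,
        coordinates=reference.coordinates[:1],
        times=reference.times[:1],
    )
    _write_pdb(ref_frame, Path(path), bfactors=np.round(clipped, 2))
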