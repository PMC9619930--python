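"""Conformer ensemble I/O and geometry sanity screening.

Conformer geometries travel as multi-frame XYZ (one frame per conformer, the
comment line carrying ``molecule_id conformer_id``).  Per-conformer chemical
potentials travel as delimited tables keyed by (molecule_id, conformer_id)
with one column per solvent.  A light geometric screen flags conformers with
overlapping or detached atoms, the kind of defective geometry that otherwise
produces wildly wrong descriptor values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConformerRecord",
    "EnsembleDataset",
    "SanityReport",
    "DEFAULT_ELEMENTS",
    "COVALENT_RADII",
    "read_xyz_ensemble",
    "write_xyz_ensemble",
    "read_target_table",
    "write_target_table",
    "geometry_sanity_check",
    "split_by_molecule",
]

#: Elements supported by default (the model covers C/H/O compounds).
DEFAULT_ELEMENTS: tuple[str, ...] = ("C", "H", "O")

#: Covalent radii in Angstrom (Cordero et al. values for the supported set).
COVALENT_RADII: dict[str, float] = {"H": 0.31, "C": 0.76, "O": 0.66}

ATOMIC_NUMBERS: dict[str, int] = {"H": 1, "C": 6, "O": 8}


@dataclass(frozen=True)
class ConformerRecord:
    """One 3-D conformer of one molecule.

    Parameters
    ----------
    molecule_id, conformer_id:
        Identity; ``conformer_id`` is unique within a molecule.
    elements:
        Element symbols, capitalized (e.g. ``("O", "H", "H")``).
    coords:
        Cartesian coordinates in Angstrom, shape ``(n_atoms, 3)``.
    provenance:
        Free-text tag naming the source (file, generator, ...).
    """

    molecule_id: str
    conformer_id: str
    elements: tuple[str, ...]
    coords: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.elements) != coords.shape[0]:
            raise ValueError(
                f"{len(self.elements)} elements but {coords.shape[0]} coordinate rows"
            )
        if len(self.elements) < 1:
            raise ValueError("a conformer needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))

    @property
    def key(self) -> tuple[str, str]:
        return (self.molecule_id, self.conformer_id)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def validate_elements(self, allowed: Iterable[str] = DEFAULT_ELEMENTS) -> None:
        allowed_set = set(allowed)
        for symbol in self.elements:
            if symbol not in allowed_set:
                raise ValueError(
                    f"unsupported element {symbol!r} in conformer "
                    f"{self.molecule_id}/{self.conformer_id}; allowed: {sorted(allowed_set)}"
                )


@dataclass
class EnsembleDataset:
    """A conformer ensemble with optional targets and a molecule-level split.

    ``split`` maps molecule_id -> "train" | "test"; splitting is always by
    molecule so that no molecule contributes conformers to both partitions.
    """

    conformers: list[ConformerRecord]
    targets: pd.DataFrame | None = None
    split: dict[str, str] = field(default_factory=dict)
    metadata: pd.DataFrame | None = None  # e.g. true H-bond counts from a generator

    def __post_init__(self) -> None:
        keys = [r.key for r in self.conformers]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (molecule_id, conformer_id) keys in ensemble")

    @property
    def keys(self) -> list[tuple[str, str]]:
        return [r.key for r in self.conformers]

    def subset(self, tag: str) -> "EnsembleDataset":
        """Return the sub-ensemble whose molecules carry split tag ``tag``."""
        records = [r for r in self.conformers if self.split.get(r.molecule_id) == tag]
        keys = [r.key for r in records]
        targets = self.targets.loc[keys] if self.targets is not None else None
        metadata = self.metadata.loc[keys] if self.metadata is not None else None
        return EnsembleDataset(records, targets, dict(self.split), metadata)


def _normalize_symbol(raw: str) -> str:
    return raw.strip().capitalize()


def read_xyz_ensemble(
    path: str | Path,
    id_policy: str = "comment",
    allowed_elements: Iterable[str] = DEFAULT_ELEMENTS,
) -> list[ConformerRecord]:
    """Read a multi-frame XYZ file into conformer records.

    ``id_policy`` controls identity assignment:

    * ``"comment"`` — the comment line is split as ``molecule_id conformer_id``;
      frames with uninformative comments fall back to auto-numbering.
    * ``"auto"`` — ignore comments; ids are ``mol0/0``, ``mol0/1``, ... with all
      frames assigned to one molecule, in file order (file order is canonical
      for the stride subsample).
    """
    path = Path(path)
    if path.suffix.lower() in (".sdf", ".mol"):
        raise NotImplementedError(
            f"{path}: SDF/MOL input is not supported in this version; "
            "convert to multi-frame XYZ first"
        )
    lines = path.read_text().splitlines()
    records: list[ConformerRecord] = []
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(
                f"frame {frame_index} in {path}: expected atom count, got {lines[pos]!r}"
            ) from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        elements: list[str] = []
        coords: list[list[float]] = []
        for j in range(natoms):
            row_idx = pos + 2 + j
            if row_idx >= len(lines):
                raise ValueError(
                    f"frame {frame_index} in {path}: declares {natoms} atoms "
                    f"but file ends after {j}"
                )
            parts = lines[row_idx].split()
            if len(parts) < 4:
                raise ValueError(
                    f"frame {frame_index} in {path}: atom line {j} malformed: "
                    f"{lines[row_idx]!r}"
                )
            symbol = _normalize_symbol(parts[0])
            try:
                xyz = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ValueError(
                    f"frame {frame_index} in {path}: unparsable coordinate in "
                    f"atom line {j}: {lines[row_idx]!r}"
                ) from exc
            elements.append(symbol)
            coords.append(xyz)

        mol_id, conf_id = "mol0", str(frame_index)
        if id_policy == "comment":
            parts = comment.split()
            if len(parts) >= 2:
                mol_id, conf_id = parts[0], parts[1]
        elif id_policy != "auto":
            raise ValueError(f"unknown id_policy {id_policy!r}")

        record = ConformerRecord(
            molecule_id=mol_id,
            conformer_id=conf_id,
            elements=tuple(elements),
            coords=np.array(coords, dtype=float),
            provenance=str(path),
        )
        record.validate_elements(allowed_elements)
        records.append(record)
        pos += 2 + natoms
        frame_index += 1
    return records


def write_xyz_ensemble(records: Sequence[ConformerRecord], path: str | Path) -> None:
    """Write records as multi-frame XYZ; the comment line is the identity key."""
    path = Path(path)
    chunks: list[str] = []
    for record in records:
        chunks.append(str(record.n_atoms))
        chunks.append(f"{record.molecule_id} {record.conformer_id}")
        for symbol, (x, y, z) in zip(record.elements, record.coords):
            chunks.append(f"{symbol} {x:.8f} {y:.8f} {z:.8f}")
    path.write_text("\n".join(chunks) + ("\n" if chunks else ""))


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited target table into a DataFrame.

    Expects columns ``molecule_id``, ``conformer_id`` and one numeric column
    per solvent (chemical potential in kcal/mol).  Delimiter (comma or tab)
    is auto-detected.  Returns a DataFrame indexed by the identity pair.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str, 1: str})
    required = {"molecule_id", "conformer_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must contain molecule_id and conformer_id")
    solvents = [c for c in df.columns if c not in required]
    if not solvents:
        raise ValueError(f"{path}: no solvent columns")
    df["molecule_id"] = df["molecule_id"].astype(str)
    df["conformer_id"] = df["conformer_id"].astype(str)
    dup = df.duplicated(subset=["molecule_id", "conformer_id"])
    if dup.any():
        first = df.loc[dup, ["molecule_id", "conformer_id"]].iloc[0]
        raise ValueError(
            f"{path}: duplicate key ({first['molecule_id']}, {first['conformer_id']})"
        )
    for col in solvents:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row + 2}")
        df[col] = values
    out = df.set_index(["molecule_id", "conformer_id"])
    if not np.all(np.isfinite(out.to_numpy())):
        raise ValueError(f"{path}: non-finite chemical potential")
    return out


def write_target_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a (molecule_id, conformer_id)-indexed table as CSV."""
    out = table.reset_index()
    out.to_csv(path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class SanityReport:
    """Outcome of the geometric screen: pass/fail plus the offending pairs/atoms."""

    key: tuple[str, str]
    ok: bool
    short_contacts: tuple[tuple[int, int, float], ...]  # (i, j, distance)
    dangling_atoms: tuple[tuple[int, float], ...]  # (i, nearest-neighbour distance)

    def __bool__(self) -> bool:
        return self.ok


def geometry_sanity_check(
    record: ConformerRecord,
    min_dist_A: float = 0.7,
    max_bond_stretch: float = 1.3,
    radii: dict[str, float] | None = None,
) -> SanityReport:
    """Flag geometrically defective conformers.

    Two distance-based screens (both invariant under rigid motion):

    * short contact — any interatomic distance below ``min_dist_A``;
    * dangling atom — an atom with no partner within ``max_bond_stretch``
      times the covalent-radius sum, i.e. bonded to nothing at a plausible
      bond length.  This catches atoms displaced by a corrupted internal
      coordinate.

    Single-atom records trivially pass.
    """
    radii = radii or COVALENT_RADII
    n = record.n_atoms
    if n == 1:
        return SanityReport(record.key, True, (), ())
    coords = record.coords
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    short: list[tuple[int, int, float]] = []
    iu, ju = np.triu_indices(n, k=1)
    close = dist[iu, ju] < min_dist_A
    for i, j, d in zip(iu[close], ju[close], dist[iu, ju][close]):
        short.append((int(i), int(j), float(d)))

    dangling: list[tuple[int, float]] = []
    np.fill_diagonal(dist, np.inf)
    rad = np.array([radii.get(e, 0.77) for e in record.elements])
    limits = max_bond_stretch * (rad[:, None] + rad[None, :])
    bonded = dist < limits
    for i in np.flatnonzero(~bonded.any(axis=1)):
        dangling.append((int(i), float(dist[i].min())))

    ok = not short and not dangling
    return SanityReport(record.key, ok, tuple(short), tuple(dangling))


def split_by_molecule(
    records: Sequence[ConformerRecord],
    test_fraction: float,
    seed: int,
) -> dict[str, str]:
    """Assign molecules (never individual conformers) to train/test.

    Returns a map molecule_id -> "train" | "test".  At least one molecule goes
    to each side when ``0 < test_fraction < 1`` and there are >= 2 molecules.
    """
    if not 0.0 <= test_fraction <= 1.0:
        raise ValueError("test_fraction must be in [0, 1]")
    molecule_ids = sorted({r.molecule_id for r in records})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(molecule_ids))
    n_test = int(round(test_fraction * len(molecule_ids)))
    if 0.0 < test_fraction < 1.0 and len(molecule_ids) >= 2:
        n_test = min(max(n_test, 1), len(molecule_ids) - 1)
    test_ids = {molecule_ids[i] for i in order[:n_test]}
    return {m: ("test" if m in test_ids else "train") for m in molecule_ids}
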