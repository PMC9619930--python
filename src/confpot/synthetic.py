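"""Synthetic conformer ensembles with a known chemical-potential oracle.

Real training targets for this kind of model come from continuum-solvation
calculations on DFT-optimized conformers.  This module replaces that
pipeline with a controllable surrogate that preserves the one statistical
feature the predictor relies on: a conformer's chemical potential is driven
by its number of intramolecular hydrogen bonds (nHB), with a
solvent-dependent slope and additive Gaussian noise,

    mu_s(conformer) = a_s * nHB + b_s + Normal(0, sigma_s).

In polar solvents (water) conformers with free OH groups interact well with
the surroundings, so mu rises with nHB (positive slope); in nonpolar media
internally satisfied conformers are favoured (negative slope).

Geometries are idealized: carbon chains with hydroxyl/carbonyl decorations
built from fixed bond lengths and tetrahedral/trigonal angles, with
randomized backbone and hydroxyl torsions per conformer.  No force field is
involved — the generator only needs geometric diversity with a known,
geometry-computable mu driver, not physical energies.  Clashing torsion
draws are rejected so every emitted conformer passes the geometry sanity
screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_structures import ConformerRecord, EnsembleDataset

__all__ = [
    "SolventParams",
    "SyntheticSpec",
    "generate_ensemble",
    "count_intramolecular_hbonds",
]

# idealized internal coordinates (Angstrom / degrees)
_R_CC = 1.52
_R_CO = 1.43
_R_C_DBL_O = 1.22
_R_CH = 1.09
_R_OH = 0.96
_ANG_TET = 109.47
_ANG_SP2 = 120.0
_ANG_COH = 104.5
_CLASH_MIN_A = 0.85  # rejection threshold for any interatomic distance


@dataclass(frozen=True)
class SolventParams:
    """Affine-plus-noise oracle for one solvent: mu = slope*nHB + intercept + noise."""

    slope: float  # kcal/mol per intramolecular H-bond
    intercept: float  # kcal/mol
    noise: float  # Gaussian sigma, kcal/mol

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise sigma must be >= 0")


def _default_solvents() -> dict[str, SolventParams]:
    # water: H-bonded conformers lose favourable solvent interactions (positive
    # slope); pure compound / organic matter: the reverse, weaker.
    return {
        "water": SolventParams(1.5, -6.0, 0.5),
        "pure": SolventParams(-0.5, -3.0, 0.5),
        "wiom": SolventParams(-0.5, -4.0, 0.5),
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic ensemble.

    ``chain_length_range`` bounds the number of backbone carbons (inclusive);
    ``torsion_count_range`` bounds how many backbone torsions are randomized
    per conformer (the rest stay anti); ``hydroxyl_range`` bounds the number
    of OH decorations per molecule.  ``hbond_cutoff_A`` is the maximum
    H...O distance counted as an intramolecular hydrogen bond;
    ``hbond_covalent_A`` separates covalent O-H bonds from contacts.

    ``aim_probability`` is the chance that a hydroxyl hydrogen is oriented
    toward its nearest acceptor oxygen rather than drawn uniformly.  It
    emulates energy-minimized ensembles, where an OH group either forms a
    hydrogen bond near its optimal geometry or points away entirely;
    uniform torsions would instead pile contacts onto the counting cutoff,
    where the H-bond count is not a learnable function of geometry.
    ``hbond_margin_A`` enforces that separation: torsion draws leaving any
    donor H...O contact within the band cutoff +- margin are resampled, so
    every emitted conformer's H-bond count is stable to ~0.3 A geometry
    perturbations (set 0 to disable).
    """

    n_molecules: int = 50
    conformers_per_molecule: int = 20
    chain_length_range: tuple[int, int] = (6, 10)
    torsion_count_range: tuple[int, int] = (2, 3)
    hydroxyl_range: tuple[int, int] = (4, 6)
    carbonyl_probability: float = 0.5
    ether_probability: float = 0.0
    aim_probability: float = 1.0
    solvent_params: dict[str, SolventParams] = field(default_factory=_default_solvents)
    hbond_cutoff_A: float = 2.5
    hbond_covalent_A: float = 1.2
    hbond_margin_A: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1 or self.conformers_per_molecule < 1:
            raise ValueError("counts must be >= 1")
        if self.chain_length_range[0] < 3:
            raise ValueError("chains need at least 3 backbone atoms")
        if self.chain_length_range[0] > self.chain_length_range[1]:
            raise ValueError("invalid chain_length_range")
        if self.hbond_cutoff_A <= self.hbond_covalent_A:
            raise ValueError("H-bond cutoff must exceed the covalent O-H threshold")
        if not self.solvent_params:
            raise ValueError("at least one solvent required")


def _place_atom(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                r: float, theta_deg: float, tau_deg: float | np.ndarray) -> np.ndarray:
    """NeRF placement: new atom bonded to p3 with angle(new,p3,p2)=theta and
    dihedral(new,p3,p2,p1)=tau.  ``tau_deg`` may be an array, returning one
    candidate position per torsion value."""
    theta = math.radians(theta_deg)
    tau = np.radians(np.asarray(tau_deg, dtype=float))
    b1 = p2 - p1
    b2 = p3 - p2
    b2n = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2n)
    d = r * (-math.cos(theta) * b2n
             + math.sin(theta) * (np.multiply.outer(np.cos(tau), m)
                                  + np.multiply.outer(np.sin(tau), n)))
    return p3 + d


@dataclass
class _ZEntry:
    element: str
    refs: tuple[int, int, int]  # (dihedral ref, angle ref, bond ref)
    r: float
    theta: float
    tau_fixed: float | None  # None => variable torsion, index below
    tau_var: int = -1


@dataclass
class _MoleculeTemplate:
    """A molecule as a z-matrix; conformers differ only in variable torsions."""

    elements: list[str]
    entries: list[_ZEntry | None]  # None for the 3 seed atoms
    n_var: int
    oh_hydrogens: list[int]  # atom indices of hydroxyl hydrogens

    def realize(self, torsions: Sequence[float]) -> np.ndarray:
        coords = np.zeros((len(self.elements), 3))
        coords[1] = (_R_CC, 0.0, 0.0)
        ang = math.radians(180.0 - _ANG_TET)
        coords[2] = coords[1] + _R_CC * np.array([math.cos(ang), math.sin(ang), 0.0])
        for i, entry in enumerate(self.entries):
            if entry is None:
                continue
            tau = entry.tau_fixed if entry.tau_fixed is not None else torsions[entry.tau_var]
            i1, i2, i3 = entry.refs
            coords[i] = _place_atom(coords[i1], coords[i2], coords[i3],
                                    entry.r, entry.theta, tau)
        return coords


def _build_template(backbone: Sequence[str], oh_positions: Sequence[int],
                    has_terminal_carbonyl: bool, n_random_backbone: int,
                    rng: np.random.Generator) -> _MoleculeTemplate:
    """Z-matrix for one molecule: a C/O backbone (ether oxygens carry no
    substituents), hydroxyl/carbonyl decorations on carbons, hydrogens
    filling carbon valence."""
    n_bb = len(backbone)

    def bond_r(i: int, j: int) -> float:
        return _R_CO if "O" in (backbone[i], backbone[j]) else _R_CC

    elements: list[str] = [backbone[0], backbone[1], backbone[2]]
    entries: list[_ZEntry | None] = [None, None, None]
    n_var = 0

    # backbone atoms 3..n-1; a random subset of their torsions varies per
    # conformer, the rest are anti (180 deg)
    bb_torsion_atoms = list(range(3, n_bb))
    rng.shuffle(bb_torsion_atoms)
    variable_bb = set(bb_torsion_atoms[:n_random_backbone])
    for i in range(3, n_bb):
        tau = (None, n_var) if i in variable_bb else (180.0, -1)
        entries.append(_ZEntry(backbone[i], (i - 3, i - 2, i - 1),
                               bond_r(i - 1, i), _ANG_TET, tau[0], tau[1]))
        elements.append(backbone[i])
        if tau[0] is None:
            n_var += 1

    def sub_frame(ci: int) -> tuple[tuple[int, int, int], list[float]]:
        """Reference triple and available torsion slots for carbon ci's substituents."""
        if ci == 0:
            return (2, 1, 0), [60.0, 180.0, 300.0]
        if ci == n_bb - 1:
            return (ci - 2, ci - 1, ci), [60.0, 180.0, 300.0]
        # internal: two tetrahedral slots flanking the backbone plane
        return (ci + 1, ci - 1, ci), [118.0, -118.0]

    oh_hydrogens: list[tuple[int, int]] = []  # (O index, parent C) to get an H later
    for ci in range(n_bb):
        if backbone[ci] == "O":
            continue  # ether oxygen: both valences used by the backbone
        refs, slots = sub_frame(ci)
        slot_iter = iter(slots)
        if has_terminal_carbonyl and ci == n_bb - 1:
            # aldehyde-like terminus: C(=O)H, trigonal
            elements.append("O")
            entries.append(_ZEntry("O", refs, _R_C_DBL_O, _ANG_SP2, 180.0))
            elements.append("H")
            entries.append(_ZEntry("H", refs, _R_CH, _ANG_SP2, 0.0))
            continue
        if ci in oh_positions:
            o_idx = len(elements)
            elements.append("O")
            entries.append(_ZEntry("O", refs, _R_CO, _ANG_TET, next(slot_iter)))
            oh_hydrogens.append((o_idx, ci))
        for tau in slot_iter:
            elements.append("H")
            entries.append(_ZEntry("H", refs, _R_CH, _ANG_TET, tau))

    # hydroxyl hydrogens: torsion randomized per conformer (the main nHB dial)
    oh_h_indices: list[int] = []
    for o_idx, ci in oh_hydrogens:
        other = ci - 1 if ci > 0 else ci + 1
        oh_h_indices.append(len(elements))
        elements.append("H")
        entries.append(_ZEntry("H", (other, ci, o_idx), _R_OH, _ANG_COH, None, n_var))
        n_var += 1

    return _MoleculeTemplate(elements, entries, n_var, oh_h_indices)


def _place_hydroxyl_hydrogens(template: _MoleculeTemplate, coords: np.ndarray,
                              rng: np.random.Generator,
                              spec: "SyntheticSpec") -> bool:
    """Choose each hydroxyl-H torsion from a candidate grid, enforcing the
    H-bond margin band and clash limits.

    With probability ``aim_probability`` the hydrogen takes the valid torsion
    closest to its nearest acceptor oxygen (forming an H-bond whenever the
    backbone geometry allows one); otherwise a random valid torsion.  Valid
    means: no interatomic distance below the clash limit and no acceptor
    contact inside the counting margin band.  Heavy atoms are already fixed,
    so donors are handled independently.  Returns False if some hydrogen has
    no valid torsion (caller resamples the backbone).
    """
    o_all = np.array([i for i, e in enumerate(template.elements) if e == "O"], dtype=int)
    band_lo = spec.hbond_cutoff_A - spec.hbond_margin_A
    band_hi = spec.hbond_cutoff_A + spec.hbond_margin_A
    others_mask = np.ones(len(coords), dtype=bool)
    for h_idx in template.oh_hydrogens:
        entry = template.entries[h_idx]
        donor_o = entry.refs[2]
        p1, p2, p3 = coords[entry.refs[0]], coords[entry.refs[1]], coords[donor_o]
        taus = np.arange(0.0, 360.0, 15.0) + rng.uniform(0.0, 15.0)
        cand = _place_atom(p1, p2, p3, entry.r, entry.theta, taus)  # (K, 3)
        others_mask[:] = True
        others_mask[h_idx] = False
        others_mask[donor_o] = False
        d_other = np.linalg.norm(cand[:, None, :] - coords[None, others_mask, :], axis=-1)
        valid = d_other.min(axis=1) >= _CLASH_MIN_A
        acceptors = o_all[o_all != donor_o]
        if acceptors.size and spec.hbond_margin_A > 0:
            d_acc = np.linalg.norm(cand[:, None, :] - coords[None, acceptors, :], axis=-1)
            valid &= ~np.any((d_acc > band_lo) & (d_acc < band_hi), axis=1)
        if not valid.any():
            return False
        idx_valid = np.flatnonzero(valid)
        if acceptors.size and rng.random() < spec.aim_probability:
            d_near = np.linalg.norm(
                cand[idx_valid][:, None, :] - coords[None, acceptors, :], axis=-1
            ).min(axis=1)
            choice = idx_valid[int(np.argmin(d_near))]
        else:
            choice = int(rng.choice(idx_valid))
        coords[h_idx] = cand[choice]
    return True


def _sample_conformer(template: _MoleculeTemplate, rng: np.random.Generator,
                      spec: "SyntheticSpec", max_tries: int = 100) -> np.ndarray:
    """Draw backbone torsions until clash-free, then orient hydroxyl
    hydrogens; fall back to the extended anti chain."""
    for _ in range(max_tries):
        torsions = rng.uniform(-180.0, 180.0, size=template.n_var)
        coords = template.realize(torsions)
        # clash check on everything but the hydroxyl H's (placed next)
        keep = np.ones(len(coords), dtype=bool)
        keep[template.oh_hydrogens] = False
        sub = coords[keep]
        diff = sub[:, None, :] - sub[None, :, :]
        dist = np.sqrt(np.sum(diff * diff, axis=-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() < _CLASH_MIN_A:
            continue
        if _place_hydroxyl_hydrogens(template, coords, rng, spec):
            return coords
    coords = template.realize(np.full(template.n_var, 180.0))
    _place_hydroxyl_hydrogens(template, coords, rng, spec)
    return coords


def count_intramolecular_hbonds(
    record: ConformerRecord,
    cutoff_A: float = 2.5,
    covalent_A: float = 1.2,
) -> int:
    """Count O-H...O contacts inside one conformer.

    A hydrogen covalently bound to an oxygen (distance < ``covalent_A``)
    donates one H-bond to every *other* oxygen within ``cutoff_A`` (but
    beyond the covalent threshold).  Purely distance-based — no angle
    criterion — so the count is invariant under rigid motion.
    """
    elements = np.array(record.elements)
    o_idx = np.flatnonzero(elements == "O")
    h_idx = np.flatnonzero(elements == "H")
    if o_idx.size == 0 or h_idx.size == 0:
        return 0
    d = np.linalg.norm(
        record.coords[h_idx][:, None, :] - record.coords[o_idx][None, :, :], axis=-1
    )
    donors = (d < covalent_A).any(axis=1)
    contacts = (d > covalent_A) & (d <= cutoff_A)
    return int(contacts[donors].sum())


def generate_ensemble(spec: SyntheticSpec) -> EnsembleDataset:
    """Generate a reproducible ensemble with targets and ground-truth metadata.

    Returns an :class:`EnsembleDataset` whose ``targets`` hold the noisy
    per-solvent mu values (kcal/mol) and whose ``metadata`` records, per
    conformer, the true H-bond count ``nhb`` and the noise-free
    ``true_<solvent>`` values for assertions and oracle-based evaluation.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ConformerRecord] = []
    meta_rows: list[dict] = []
    target_rows: list[dict] = []

    for mi in range(spec.n_molecules):
        n_heavy = int(rng.integers(spec.chain_length_range[0], spec.chain_length_range[1] + 1))
        # C/O backbone: internal positions become ether oxygens with
        # probability ether_probability, never adjacent to each other
        backbone = ["C"] * n_heavy
        for i in range(1, n_heavy - 1):
            if backbone[i - 1] != "O" and rng.random() < spec.ether_probability:
                backbone[i] = "O"
        has_cho = bool(rng.random() < spec.carbonyl_probability)
        carbon_sites = [i for i in range(n_heavy)
                        if backbone[i] == "C" and not (has_cho and i == n_heavy - 1)]
        lo, hi = spec.hydroxyl_range
        n_oh = min(int(rng.integers(lo, hi + 1)), len(carbon_sites))
        # hydroxyls sit on consecutive carbon sites (polyol motif): vicinal
        # OH pairs are what make the intramolecular H-bond count swing with
        # conformation, the statistical structure the model has to learn
        start = int(rng.integers(0, len(carbon_sites) - n_oh + 1))
        oh_positions = carbon_sites[start : start + n_oh]
        t_lo, t_hi = spec.torsion_count_range
        n_rand = min(int(rng.integers(t_lo, t_hi + 1)), max(n_heavy - 3, 0))
        template = _build_template(backbone, oh_positions, has_cho, n_rand, rng)
        mol_id = f"mol{mi:04d}"

        for ci in range(spec.conformers_per_molecule):
            coords = _sample_conformer(template, rng, spec)
            record = ConformerRecord(
                molecule_id=mol_id,
                conformer_id=str(ci),
                elements=tuple(template.elements),
                coords=coords,
                provenance="confpot-synthetic",
            )
            records.append(record)
            nhb = count_intramolecular_hbonds(
                record, spec.hbond_cutoff_A, spec.hbond_covalent_A
            )
            meta = {"molecule_id": mol_id, "conformer_id": str(ci), "nhb": nhb}
            targets = {"molecule_id": mol_id, "conformer_id": str(ci)}
            for label, sp in spec.solvent_params.items():
                true_mu = sp.slope * nhb + sp.intercept
                meta[f"true_{label}"] = true_mu
                targets[label] = true_mu + rng.normal(0.0, sp.noise)
            meta_rows.append(meta)
            target_rows.append(targets)

    index_cols = ["molecule_id", "conformer_id"]
    targets_df = pd.DataFrame(target_rows).set_index(index_cols)
    meta_df = pd.DataFrame(meta_rows).set_index(index_cols)
    return EnsembleDataset(records, targets_df, {}, meta_df)
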