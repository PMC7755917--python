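"""Synthetic branched-filament models with known ground truth.

Real branch-junction models are large deposited structures; to make every
analysis stage testable without downloads this module builds idealised stand-in
models whose geometry is known exactly:

* a *toy monomer* — a seeded random cloud of Calpha pseudo-atoms within a
  radius, with one designated on-axis reference atom (Calpha of residue 269,
  mirroring actin's Met269) at the local origin;
* helical *filaments* — the monomer repeated under a rise/twist screw
  operation along +z (defaults 27.5 Å / -166.7° per subunit, resembling
  canonical F-actin geometry; these are generator defaults, not measured
  values);
* a *branch*: a mother filament of 8 subunits (M1..M8), a daughter of 3
  (D1..D3) whose axis subtends an exact prescribed angle with the mother
  axis, and optionally seven labelled "complex" blobs (ARP2..ARPC5) placed at
  the junction so contact and buried-area analyses have a complex group;
* i.i.d. Gaussian coordinate noise, seeded and reproducible.

Every build returns a ground-truth record sufficient to re-derive the
expected analysis outputs (branch angle, axes, subunit transforms, blob
centres) without re-running the generator.  All outputs are plain
:class:`~branchkit.io.BranchModel` objects and round-trip through the PDB
writer at 3-decimal coordinate precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import ATOM_COLUMNS, AtomTable, BranchModel, COMPLEX_LABELS, validate_label

REFERENCE_RESIDUE = 269
DEFAULT_RISE = 27.5  # Å per subunit, generator default
DEFAULT_TWIST = -166.7  # degrees per subunit, generator default

_AA_CYCLE = ["ALA", "GLY", "SER", "VAL", "LEU", "THR", "PRO", "ASP"]


@dataclass(frozen=True)
class FilamentSpec:
    """Helical parameters of one synthetic filament."""

    rise: float = DEFAULT_RISE
    twist: float = DEFAULT_TWIST
    n_subunits: int = 8
    role_prefix: str = "M"

    def __post_init__(self):
        if self.rise <= 0:
            raise ParameterError("rise must be positive")
        if self.n_subunits < 2:
            raise ParameterError("a filament needs at least 2 subunits")
        if self.role_prefix not in ("M", "D"):
            raise ParameterError("role_prefix must be 'M' or 'D'")

    @property
    def labels(self) -> list[str]:
        return [f"{self.role_prefix}{k}" for k in range(1, self.n_subunits + 1)]


@dataclass(frozen=True)
class BranchSpec:
    """Placement of the daughter filament relative to the mother."""

    theta: float = 71.0  # degrees, ground-truth branch angle
    attachment_subunit: str = "M4"
    daughter_offset: tuple[float, float, float] = (40.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.theta < 180.0:
            raise ParameterError("theta must lie strictly between 0 and 180 degrees")
        validate_label(self.attachment_subunit)


@dataclass
class ToyMonomer:
    """Random pseudo-atom cloud with an on-axis reference Calpha at the origin."""

    atoms: AtomTable
    seed: int
    radius: float

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def make_toy_monomer(n_atoms: int, radius: float, seed: int) -> ToyMonomer:
    """Seeded toy monomer of ``n_atoms`` Calpha pseudo-atoms within ``radius`` Å.

    Atom 0 is the designated reference: Calpha of residue 269 at the local
    origin (playing the role of actin's on-axis Met269).  The remaining atoms
    are Calpha atoms of residues 1..n_atoms-1, uniformly distributed in the
    ball of the given radius, with residue names cycled deterministically.
    """
    if n_atoms < 4:
        raise ParameterError(f"a monomer needs at least 4 atoms, got {n_atoms}")
    rng = np.random.default_rng(seed)
    # uniform in the ball via rejection-free radial scaling
    directions = rng.normal(size=(n_atoms - 1, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = radius * rng.random(n_atoms - 1) ** (1.0 / 3.0)
    xyz = np.vstack([[0.0, 0.0, 0.0], directions * radii[:, None]])
    resnums = [REFERENCE_RESIDUE] + list(range(1, n_atoms))
    rows = [
        (
            "A",
            resnums[i],
            "",
            "MET" if resnums[i] == REFERENCE_RESIDUE else _AA_CYCLE[i % len(_AA_CYCLE)],
            "CA",
            "C",
            xyz[i, 0],
            xyz[i, 1],
            xyz[i, 2],
            1.0,
            "",
            True,
        )
        for i in range(n_atoms)
    ]
    table = AtomTable(pd.DataFrame(rows, columns=ATOM_COLUMNS))
    return ToyMonomer(table, seed=seed, radius=radius)


def _rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def build_filament(monomer: ToyMonomer, spec: FilamentSpec) -> BranchModel:
    """Helical filament: subunit k is the monomer rotated by k*twist about +z
    and translated k*rise along it; reference atoms therefore sit exactly on
    the +z axis at z = 0, rise, 2*rise, ..."""
    base = monomer.atoms.coords
    subunits = {}
    for k, label in enumerate(spec.labels):
        R = _rot_z(k * spec.twist)
        xyz = base @ R.T + np.array([0.0, 0.0, k * spec.rise])
        subunits[label] = monomer.atoms.with_coords(xyz)
    return BranchModel(subunits, provenance=f"synthetic-filament-{spec.role_prefix}")


@dataclass
class BranchTruth:
    """Ground truth of a constructed branch; enough to re-derive every
    expected analysis output without re-running the generator."""

    theta: float
    mother_axis: np.ndarray
    daughter_axis: np.ndarray
    attachment_subunit: str
    attachment_point: np.ndarray
    daughter_rotation: np.ndarray  # applied to daughter construction frame
    daughter_translation: np.ndarray
    complex_centers: dict[str, np.ndarray] = field(default_factory=dict)
    mother_spec: FilamentSpec | None = None
    daughter_spec: FilamentSpec | None = None
    monomer_seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "theta_deg": self.theta,
            "mother_axis": self.mother_axis.tolist(),
            "daughter_axis": self.daughter_axis.tolist(),
            "attachment_subunit": self.attachment_subunit,
            "attachment_point": self.attachment_point.tolist(),
            "daughter_rotation": self.daughter_rotation.tolist(),
            "daughter_translation": self.daughter_translation.tolist(),
            "complex_centers": {k: v.tolist() for k, v in self.complex_centers.items()},
            "mother_spec": vars(self.mother_spec) if self.mother_spec else None,
            "daughter_spec": vars(self.daughter_spec) if self.daughter_spec else None,
            "monomer_seed": self.monomer_seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def build_branch(
    mother: FilamentSpec,
    daughter: FilamentSpec,
    branch: BranchSpec,
    monomer: ToyMonomer,
    complex_monomers: dict[str, ToyMonomer] | None = None,
    complex_centers: dict[str, np.ndarray] | None = None,
) -> tuple[BranchModel, BranchTruth]:
    """Assemble a mother filament, an angled daughter filament and optional
    complex blobs into one labelled branch model.

    The daughter filament is built along +z in its own frame, rotated by
    ``branch.theta`` about the +x axis through the attachment subunit's
    reference atom, and shifted by ``branch.daughter_offset`` — so its axis
    subtends *exactly* theta with the mother axis by construction.

    ``complex_monomers`` (label -> ToyMonomer, labels from ARP2..ARPC5) are
    placed with their reference atoms at ``complex_centers``; default centres
    form a ring of radius 25 Å around the segment between the attachment point
    and the daughter origin, so the blobs sit at the junction.
    """
    if mother.role_prefix != "M" or daughter.role_prefix != "D":
        raise ParameterError("mother spec must use prefix 'M' and daughter 'D'")
    mother_model = build_filament(monomer, mother)
    if branch.attachment_subunit not in mother_model.subunits:
        raise ParameterError(
            f"attachment subunit {branch.attachment_subunit!r} not in mother filament "
            f"(labels {mother.labels})"
        )
    attach_df = mother_model.subunits[branch.attachment_subunit].df
    ref = attach_df[attach_df["residue_number"] == REFERENCE_RESIDUE]
    attach_point = ref[["x", "y", "z"]].to_numpy(float)[0]

    R = _rot_x(branch.theta)
    offset = np.asarray(branch.daughter_offset, float)
    t = attach_point + offset  # daughter origin (D1 reference atom position)

    daughter_frame = build_filament(monomer, daughter)
    daughter_model = daughter_frame.transformed(lambda x: x @ R.T + t)

    subunits = dict(mother_model.subunits)
    subunits.update(daughter_model.subunits)

    centers: dict[str, np.ndarray] = {}
    if complex_monomers:
        bad = set(complex_monomers) - set(COMPLEX_LABELS)
        if bad:
            raise ParameterError(f"unknown complex labels: {sorted(bad)}")
        if complex_centers is None:
            complex_centers = default_complex_centers(
                attach_point, t, list(complex_monomers)
            )
        for label, mono in complex_monomers.items():
            c = np.asarray(complex_centers[label], float)
            subunits[label] = mono.atoms.with_coords(mono.atoms.coords + c)
            centers[label] = c

    model = BranchModel(subunits, provenance="synthetic-branch")
    truth = BranchTruth(
        theta=branch.theta,
        mother_axis=np.array([0.0, 0.0, 1.0]),
        daughter_axis=R @ np.array([0.0, 0.0, 1.0]),
        attachment_subunit=branch.attachment_subunit,
        attachment_point=attach_point,
        daughter_rotation=R,
        daughter_translation=t,
        complex_centers=centers,
        mother_spec=mother,
        daughter_spec=daughter,
        monomer_seed=monomer.seed,
    )
    return model, truth


def default_complex_centers(
    attach_point: np.ndarray, daughter_origin: np.ndarray, labels: list[str]
) -> dict[str, np.ndarray]:
    """Ring of blob centres around the mother-daughter junction midpoint."""
    mid = 0.5 * (np.asarray(attach_point) + np.asarray(daughter_origin))
    axis = np.asarray(daughter_origin) - np.asarray(attach_point)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    # orthonormal frame perpendicular to the junction axis
    u = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-9:
        u = np.cross(axis, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    centers = {}
    for i, label in enumerate(labels):
        ang = 2.0 * np.pi * i / max(len(labels), 1)
        centers[label] = mid + 25.0 * (np.cos(ang) * u + np.sin(ang) * v)
    return centers


def default_complex_monomers(
    n_atoms: int = 30, radius: float = 12.0, seed: int = 100
) -> dict[str, ToyMonomer]:
    """Seven seeded blobs labelled as the Arp2/3 complex subunits."""
    return {
        label: make_toy_monomer(n_atoms, radius, seed + i)
        for i, label in enumerate(COMPLEX_LABELS)
    }


def perturb_model(model: BranchModel, sigma: float, seed: int) -> BranchModel:
    """Add i.i.d. Gaussian noise (std ``sigma`` Å per coordinate) to every atom.

    ``sigma = 0`` returns an identical copy; the same seed always produces
    the same displacement field.
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be non-negative, got {sigma}")
    rng = np.random.default_rng(seed)
    subs = {}
    for label, table in model.subunits.items():
        noise = rng.normal(scale=sigma, size=(len(table), 3)) if sigma > 0 else 0.0
        subs[label] = table.with_coords(table.coords + noise)
    return BranchModel(subs, provenance=model.provenance, unmapped_chains=list(model.unmapped_chains))


def standard_branch(
    theta: float = 71.0,
    seed: int = 1,
    n_mother: int = 8,
    n_daughter: int = 3,
    rise: float = DEFAULT_RISE,
    twist: float = DEFAULT_TWIST,
    monomer_atoms: int = 50,
    monomer_radius: float = 14.0,
    with_complex: bool = True,
) -> tuple[BranchModel, BranchTruth]:
    """Convenience builder for the canonical test assembly: an 8-subunit
    mother, 3-subunit daughter and the seven complex blobs at the junction
    (18 subunits total, mirroring the composition of a real branch model)."""
    monomer = make_toy_monomer(monomer_atoms, monomer_radius, seed)
    mother = FilamentSpec(rise=rise, twist=twist, n_subunits=n_mother, role_prefix="M")
    daughter = FilamentSpec(rise=rise, twist=twist, n_subunits=n_daughter, role_prefix="D")
    spec = BranchSpec(theta=theta, attachment_subunit=f"M{min(4, n_mother)}", seed=seed)
    blobs = default_complex_monomers(seed=seed + 100) if with_complex else None
    return build_branch(mother, daughter, spec, monomer, complex_monomers=blobs)
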