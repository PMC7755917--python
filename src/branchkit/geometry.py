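"""Branch-junction geometry: filament axis vectors and the branch angle.

The filament direction is taken literally as the line between two designated
on-axis reference atoms — by default the Calpha of residue 269 (Met269 in
actin, a residue lying close to the filament's central axis) of the first and
last subunit of each filament.  The mother axis runs M1 -> M8 and the daughter
axis D1 -> D3 (pointed-end to barbed-end by label order), and the branch angle
is

    theta = arccos( v_mother . v_daughter / (|v_mother| |v_daughter|) )

reported in degrees in [0, 180].  The complement 180 - theta is carried
alongside so an orientation-convention flip can never silently report the
complement.  An alternative least-squares axis through all subunit centroids
is available but never the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ReferenceAtomError
from .io import BranchModel

DEFAULT_REFERENCE_RESIDUE = 269


@dataclass(frozen=True)
class AxisSpec:
    """Endpoints defining a filament axis by designated reference atoms."""

    from_label: str
    to_label: str
    reference_residue: int = DEFAULT_REFERENCE_RESIDUE
    reference_atom: str = "CA"

    def __post_init__(self):
        if self.from_label == self.to_label:
            raise ValueError("axis endpoints must be distinct subunits")


MOTHER_AXIS = AxisSpec("M1", "M8")
DAUGHTER_AXIS = AxisSpec("D1", "D3")


@dataclass(frozen=True)
class AtomIdentity:
    label: str
    residue_number: int
    atom_name: str
    position: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "subunit": self.label,
            "residue_number": self.residue_number,
            "atom_name": self.atom_name,
            "position": list(self.position),
        }


def _reference_atom(model: BranchModel, label: str, spec: AxisSpec) -> AtomIdentity:
    if label not in model.subunits:
        raise ReferenceAtomError(f"model has no subunit {label!r}")
    df = model.subunits[label].df
    hit = df[
        (df["atom_name"] == spec.reference_atom)
        & (df["residue_number"] == spec.reference_residue)
    ]
    if len(hit) == 0:
        raise ReferenceAtomError(
            f"subunit {label}: no {spec.reference_atom} atom at residue {spec.reference_residue}"
        )
    if len(hit) > 1:
        raise ReferenceAtomError(
            f"subunit {label}: {len(hit)} {spec.reference_atom} atoms at residue "
            f"{spec.reference_residue} (expected exactly 1)"
        )
    row = hit.iloc[0]
    return AtomIdentity(
        label, int(row["residue_number"]), row["atom_name"], (row["x"], row["y"], row["z"])
    )


def axis_vector(
    model: BranchModel, spec: AxisSpec
) -> tuple[np.ndarray, tuple[AtomIdentity, AtomIdentity]]:
    """Unit vector from the from-subunit reference atom to the to-subunit one."""
    a = _reference_atom(model, spec.from_label, spec)
    b = _reference_atom(model, spec.to_label, spec)
    v = np.asarray(b.position, float) - np.asarray(a.position, float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ReferenceAtomError(
            f"reference atoms of {spec.from_label} and {spec.to_label} coincide"
        )
    return v / norm, (a, b)


def axis_vector_centroids(model: BranchModel, labels: list[str]) -> np.ndarray:
    """Least-squares line through the subunit centroids (optional estimator).

    The principal direction of the centroid cloud, oriented from the first
    label's centroid towards the last's.  Not used by default.
    """
    cents = np.array([model.subunits[l].coords.mean(axis=0) for l in labels])
    centered = cents - cents.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    v = vt[0]
    if np.dot(v, cents[-1] - cents[0]) < 0:
        v = -v
    return v / np.linalg.norm(v)


@dataclass
class BranchAngleResult:
    """Mother-daughter branch angle and the vectors/atoms that produced it."""

    theta: float  # degrees in [0, 180]
    mother_vector: np.ndarray
    daughter_vector: np.ndarray
    atoms_used: list[AtomIdentity] = field(default_factory=list)

    @property
    def complement(self) -> float:
        return 180.0 - self.theta

    def to_dict(self) -> dict:
        return {
            "theta_deg": self.theta,
            "complement_deg": self.complement,
            "mother_vector": self.mother_vector.tolist(),
            "daughter_vector": self.daughter_vector.tolist(),
            "atoms_used": [a.to_dict() for a in self.atoms_used],
        }

    def __repr__(self) -> str:
        return f"BranchAngleResult(theta={self.theta:.1f} deg)"


def branch_angle(
    model: BranchModel,
    mother_spec: AxisSpec = MOTHER_AXIS,
    daughter_spec: AxisSpec = DAUGHTER_AXIS,
) -> BranchAngleResult:
    """Branch angle between the mother and daughter filament axis vectors.

    The dot product of the two unit vectors is clamped to [-1, 1] before the
    arccos, so antiparallel axes at the edge of floating-point range cannot
    produce NaN.
    """
    vm, (ma, mb) = axis_vector(model, mother_spec)
    vd, (da, db) = axis_vector(model, daughter_spec)
    cos_theta = float(np.clip(np.dot(vm, vd), -1.0, 1.0))
    theta = float(np.degrees(np.arccos(cos_theta)))
    return BranchAngleResult(theta, vm, vd, [ma, mb, da, db])
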