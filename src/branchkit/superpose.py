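"""Least-squares rigid superposition and Calpha RMSD analyses.

The workhorse is the Kabsch algorithm: given two equal-length ordered point
sets, find the proper rotation ``R`` (det = +1, reflections excluded — protein
chirality is physical) and translation ``t`` minimising the sum of squared
distances.  On top of it sit per-subunit RMSD between two conformations and
the anchored RMSD matrix: for each *anchor* subunit the full model is
superposed using only that subunit's paired Calpha atoms, and the RMSD of every
other subunit is measured under that single transform.  Off-diagonal structure
of the matrix reveals which groups of subunits move as rigid bodies relative
to each other, e.g. the two Arp2/3 subcomplexes that rotate against one
another upon activation.

All RMSDs are over paired Calpha atoms only.  Pairing is by residue number
(the default, suited to models that share numbering) or by global sequence
alignment with identity scoring (for structures with independent numbering).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.SeqUtils import seq1

from .errors import DegeneracyError, PairingError
from .io import AtomTable, BranchModel, select_atoms


@dataclass(frozen=True)
class Transform:
    """Proper rigid-body transform ``x -> R @ x + t`` (rotation then translation)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation has det != +1 (reflection)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ np.asarray(self.rotation).T + np.asarray(
            self.translation
        )

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[Transform, float]:
    """Least-squares superposition of ``moving`` onto ``fixed``.

    Returns the proper rigid transform minimising the summed squared
    distances between corresponding points, and the post-fit RMSD in Å.
    Raises :class:`PairingError` on length mismatch and
    :class:`DegeneracyError` for fewer than 3 points or collinear sets
    (where the in-plane rotation would be arbitrary).
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise PairingError(
            f"point sets must be equal-length (n, 3) arrays, got {moving.shape} vs {fixed.shape}"
        )
    n = len(moving)
    if n < 3:
        raise DegeneracyError(f"need >= 3 points for superposition, got {n}")
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    P, Q = moving - mc, fixed - fc
    for name, X in (("moving", P), ("fixed", Q)):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-9 * max(1.0, s[0]):
            raise DegeneracyError(f"{name} point set is (near-)collinear")
    H = P.T @ Q
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])  # flip smallest singular direction if improper
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    tr = Transform(R, t)
    return tr, _rmsd(tr.apply(moving), fixed)


# ---------------------------------------------------------------------------
# Calpha pairing

_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1.0
_ALIGNER.mismatch_score = 0.0
_ALIGNER.open_gap_score = -0.5
_ALIGNER.extend_gap_score = -0.1


def _ca_frame(table: AtomTable) -> pd.DataFrame:
    df = table.df
    df = df[df["atom_name"] == "CA"]
    df = df.sort_values(["residue_number", "insertion_code"], kind="mergesort")
    if df.empty:
        raise PairingError("subunit contains no Calpha atoms")
    return df


def pair_common_ca(
    sub_a: AtomTable, sub_b: AtomTable, mode: str = "residue_number"
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Pair the Calpha atoms of two subunits.

    ``residue_number`` pairs the intersection of (residue number, insertion
    code) keys; ``sequence_alignment`` pairs via a global alignment of the two
    residue-name sequences with identity scoring, which handles independent
    numbering.  Returns two equal-length coordinate arrays plus a table of the
    paired residues.
    """
    a, b = _ca_frame(sub_a), _ca_frame(sub_b)
    if mode == "residue_number":
        keys_a = list(zip(a["residue_number"], a["insertion_code"]))
        keys_b = list(zip(b["residue_number"], b["insertion_code"]))
        common = sorted(set(keys_a) & set(keys_b))
        if not common:
            raise PairingError("no common residue numbers between subunits")
        ia = {k: i for i, k in enumerate(keys_a)}
        ib = {k: i for i, k in enumerate(keys_b)}
        idx_a = [ia[k] for k in common]
        idx_b = [ib[k] for k in common]
    elif mode == "sequence_alignment":
        seq_a = seq1("".join(a["residue_name"]), undef_code="X")
        seq_b = seq1("".join(b["residue_name"]), undef_code="X")
        aln = _ALIGNER.align(seq_a, seq_b)[0]
        idx_a, idx_b = [], []
        for (sa, ea), (sb, eb) in zip(*aln.aligned):
            idx_a.extend(range(sa, ea))
            idx_b.extend(range(sb, eb))
        if not idx_a:
            raise PairingError("sequence alignment produced no aligned residues")
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    ca = a.iloc[idx_a]
    cb = b.iloc[idx_b]
    paired = pd.DataFrame(
        {
            "residue_a": ca["residue_number"].to_numpy(),
            "name_a": ca["residue_name"].to_numpy(),
            "residue_b": cb["residue_number"].to_numpy(),
            "name_b": cb["residue_name"].to_numpy(),
        }
    )
    return (
        ca[["x", "y", "z"]].to_numpy(float),
        cb[["x", "y", "z"]].to_numpy(float),
        paired,
    )


def rmsd_between_subunits(
    model: BranchModel,
    label: str,
    reference: AtomTable,
    pairing: str = "residue_number",
    prune: bool = False,
    prune_factor: float = 2.0,
    max_prune_iter: int = 10,
) -> tuple[float, int]:
    """Post-fit Calpha RMSD between one subunit of ``model`` and a reference subunit.

    The pair is superposed on its own paired Calpha atoms before measuring.
    With ``prune=True`` an iterative outlier rejection is applied (pairs
    farther than ``prune_factor`` times the current RMSD are dropped and the
    fit repeated), mimicking alignment tools that trim divergent loops; the
    default is the no-pruning value over all common Calpha atoms.  Returns
    (RMSD in Å, number of pairs used).
    """
    sub = model.subunits[label]
    mov, fix, _ = pair_common_ca(sub, reference, mode=pairing)
    _, rmsd = kabsch_superpose(mov, fix)
    n = len(mov)
    if prune:
        for _ in range(max_prune_iter):
            tr, rmsd = kabsch_superpose(mov, fix)
            dist = np.linalg.norm(tr.apply(mov) - fix, axis=1)
            keep = dist <= prune_factor * max(rmsd, 1e-6)
            if keep.all() or keep.sum() < 3:
                break
            mov, fix = mov[keep], fix[keep]
        n = len(mov)
    return rmsd, n


@dataclass
class RMSDMatrix:
    """Anchor-subunit x measured-subunit grid of Calpha RMSD values (Å).

    Row ``r``: the two models were superposed using only the paired Calpha
    atoms of subunit ``r``; entry (r, c) is subunit ``c``'s RMSD under that
    single whole-model transform.
    """

    anchors: list[str]
    targets: list[str]
    values: np.ndarray  # (n_anchors, n_targets), Å
    n_pairs: np.ndarray  # pairs per target column
    pairing_mode: str = "residue_number"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("RMSD values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.anchors, columns=self.targets)

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            (a, t, self.values[i, j], int(self.n_pairs[j]))
            for i, a in enumerate(self.anchors)
            for j, t in enumerate(self.targets)
        ]
        return pd.DataFrame(rows, columns=["anchor", "target", "rmsd", "n_pairs"])

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "anchors": self.anchors,
            "targets": self.targets,
            "values": self.values.tolist(),
            "n_pairs": [int(n) for n in self.n_pairs],
            "pairing_mode": self.pairing_mode,
        }


def anchored_rmsd_matrix(
    model_a: BranchModel,
    model_b: BranchModel,
    labels: Sequence[str],
    pairing: str = "residue_number",
) -> RMSDMatrix:
    """Anchored RMSD matrix between two conformations of the same assembly.

    For each anchor label the transform superposing ``model_a`` onto
    ``model_b`` is computed from that subunit's paired Calpha atoms alone and
    applied to all of ``model_a``; entry (anchor, target) is the Calpha RMSD of
    the target subunit under that transform.  Comparing a model with itself
    yields the zero matrix.
    """
    labels = list(labels)
    pairs = {}
    for label in labels:
        if label not in model_a.subunits or label not in model_b.subunits:
            raise PairingError(f"subunit {label!r} missing from one of the models")
        try:
            pairs[label] = pair_common_ca(
                model_a.subunits[label], model_b.subunits[label], mode=pairing
            )
        except PairingError as exc:
            raise PairingError(f"subunit {label!r}: {exc}") from exc
    values = np.zeros((len(labels), len(labels)))
    for i, anchor in enumerate(labels):
        mov, fix, _ = pairs[anchor]
        tr, _ = kabsch_superpose(mov, fix)
        for j, target in enumerate(labels):
            tmov, tfix, _ = pairs[target]
            values[i, j] = _rmsd(tr.apply(tmov), tfix)
    n_pairs = np.array([len(pairs[label][0]) for label in labels])
    return RMSDMatrix(labels, list(labels), values, n_pairs, pairing_mode=pairing)
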