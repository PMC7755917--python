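"""Structure I/O: PDB/mmCIF parsing, chain-to-subunit mapping, atom selection.

Atomic models are held in a flat :class:`AtomTable` (a thin wrapper around a
pandas DataFrame, one row per atom, coordinates in Å).  A
:class:`SubunitMapping` partitions the table's chains into labelled subunits —
mother-filament actins ``M1..Mn``, daughter-filament actins ``D1..Dn`` and the
seven Arp2/3 complex subunits (``ARP2``, ``ARP3``, ``ARPC1``..``ARPC5``) —
yielding a :class:`BranchModel`, the container every downstream analysis
consumes.

Parsing is delegated to gemmi.  Only the first MODEL block of multi-model
files is read, and alternate conformers are collapsed to the
highest-occupancy one (ties broken by alphabetically first altloc id), so all
geometry downstream sees a single conformer.  Coordinates are Å throughout and
residue numbering is taken verbatim from the file.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    MappingError,
    MissingChainError,
    StructureParseError,
)

ATOM_COLUMNS = [
    "chain_id",
    "residue_number",
    "insertion_code",
    "residue_name",
    "atom_name",
    "element",
    "x",
    "y",
    "z",
    "occupancy",
    "altloc",
    "is_polymer",
]

_LABEL_RE = re.compile(r"^(M\d+|D\d+|ARP2|ARP3|ARPC[1-5])$")

COMPLEX_LABELS = ("ARP2", "ARP3", "ARPC1", "ARPC2", "ARPC3", "ARPC4", "ARPC5")


def role_of(label: str) -> str:
    """Role implied by a subunit label: M* -> mother, D* -> daughter, ARP* -> complex."""
    label = validate_label(label)
    if label.startswith("ARP"):
        return "complex"
    if label.startswith("M"):
        return "mother"
    return "daughter"


def validate_label(label: str) -> str:
    lab = str(label).upper()
    if not _LABEL_RE.match(lab):
        raise MappingError(
            f"invalid subunit label {label!r}: expected M<n>, D<n>, ARP2, ARP3 or ARPC1..ARPC5"
        )
    return lab


class AtomTable:
    """Flat table of atom records (one row per atom, coordinates in Å)."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ATOM_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"AtomTable missing columns: {missing}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) float array of positions in Å."""
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "AtomTable":
        """Copy of this table with positions replaced by ``xyz`` (same order)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self), 3):
            raise ValueError(f"coordinate shape {xyz.shape} != ({len(self)}, 3)")
        df = self.df.copy()
        df[["x", "y", "z"]] = xyz
        return AtomTable(df)

    @property
    def chain_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["chain_id"]))

    def polymer(self) -> "AtomTable":
        return AtomTable(self.df[self.df["is_polymer"]].copy())

    def select(
        self,
        atom_name: str | None = None,
        chain_id: str | None = None,
        residue_filter: Callable[[int], bool] | None = None,
    ) -> "AtomTable":
        df = self.df
        if chain_id is not None:
            df = df[df["chain_id"] == chain_id]
        if atom_name is not None:
            df = df[df["atom_name"] == atom_name]
        if residue_filter is not None:
            df = df[df["residue_number"].map(residue_filter)]
        return AtomTable(df.copy())

    def __repr__(self) -> str:
        return f"AtomTable({len(self)} atoms, chains {self.chain_ids})"


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    # ATOM records are authoritative; for files lacking the flag fall back to
    # the chemical-component tables.
    if res.het_flag == "A":
        return True
    if res.het_flag == "H":
        info = gemmi.find_tabulated_residue(res.name)
        return bool(info and (info.is_amino_acid() or info.is_nucleic_acid()))
    info = gemmi.find_tabulated_residue(res.name)
    return bool(info and (info.is_amino_acid() or info.is_nucleic_acid()))


def _collapse_altlocs(df: pd.DataFrame) -> pd.DataFrame:
    """Keep one conformer per atom: highest occupancy, ties -> first altloc id."""
    if (df["altloc"] == "").all():
        return df
    key = ["chain_id", "residue_number", "insertion_code", "atom_name"]
    # sort so the kept row per group is max occupancy, then min altloc
    df = df.sort_values(
        key + ["occupancy", "altloc"],
        ascending=[True, True, True, True, False, True],
        kind="mergesort",
    )
    df = df.drop_duplicates(subset=key, keep="first")
    return df.sort_index()


def read_structure(path: str | Path, format_hint: str = "auto") -> AtomTable:
    """Read all atoms of the first model block of a PDB or mmCIF file.

    Parameters
    ----------
    path : path to the structure file.
    format_hint : "pdb", "mmcif" or "auto" (detect from contents/extension).

    Returns an :class:`AtomTable`; ``table.n_polymer_chains`` reports the
    number of chains containing polymer residues.  Raises
    :class:`StructureParseError` on unreadable input and
    :class:`EmptyStructureError` if the file holds no atoms at all.  A file
    containing only non-polymer atoms (e.g. waters) returns the table with an
    empty ``polymer()`` view and emits a warning.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format_hint)
    if fmt is None:
        raise ValueError(f"format_hint must be pdb|mmcif|auto, got {format_hint!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no model block")
    model = st[0]  # first MODEL only

    rows = []
    for chain in model:
        for res in chain:
            poly = _is_polymer_residue(res)
            for atom in res:
                rows.append(
                    (
                        chain.name,
                        res.seqid.num,
                        res.seqid.icode.strip(),
                        res.name,
                        atom.name,
                        atom.element.name.upper(),
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.occ,
                        "" if atom.altloc in ("\0", "") else atom.altloc,
                        poly,
                    )
                )
    if not rows:
        raise EmptyStructureError(f"{path} contains no atoms")
    df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    df = _collapse_altlocs(df)
    table = AtomTable(df)
    n_poly = len(set(df.loc[df["is_polymer"], "chain_id"]))
    table.n_polymer_chains = n_poly
    if n_poly == 0:
        warnings.warn(f"{path} contains no polymer atoms", stacklevel=2)
    return table


@dataclass(frozen=True)
class MappingEntry:
    label: str
    chain_id: str
    residue_start: int | None = None
    residue_end: int | None = None

    def covers(self, residue_number: int) -> bool:
        if self.residue_start is not None and residue_number < self.residue_start:
            return False
        if self.residue_end is not None and residue_number > self.residue_end:
            return False
        return True


@dataclass
class SubunitMapping:
    """Chain (and optional residue range) to subunit-label assignment."""

    entries: list[MappingEntry]
    source_tag: str = ""

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise MappingError(f"duplicate subunit labels in mapping: {dup}")
        for e in self.entries:
            validate_label(e.label)
        # chain/range disjointness
        by_chain: dict[str, list[MappingEntry]] = {}
        for e in self.entries:
            by_chain.setdefault(e.chain_id, []).append(e)
        for chain, ents in by_chain.items():
            if len(ents) > 1 and any(
                e.residue_start is None and e.residue_end is None for e in ents
            ):
                raise MappingError(
                    f"chain {chain!r} mapped more than once without residue ranges"
                )
            spans = sorted(
                (e.residue_start or -(10**9), e.residue_end or 10**9) for e in ents
            )
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise MappingError(f"overlapping residue ranges on chain {chain!r}")

    @property
    def labels(self) -> list[str]:
        return [validate_label(e.label) for e in self.entries]

    @classmethod
    def identity(cls, chain_labels: dict[str, str], source_tag: str = "") -> "SubunitMapping":
        return cls(
            [MappingEntry(label, chain) for chain, label in chain_labels.items()],
            source_tag=source_tag,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SubunitMapping":
        """Parse the small key-value mapping format.

        One entry per line: ``LABEL CHAIN [START-END]``; ``#`` starts a
        comment.  Example::

            # inactive Arp2/3 complex
            ARP3  A
            ARP2  B 1-394
        """
        path = Path(path)
        entries = []
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise MappingError(f"{path}:{lineno}: expected 'LABEL CHAIN [START-END]'")
            label, chain = parts[0], parts[1]
            start = end = None
            if len(parts) == 3:
                m = re.match(r"^(-?\d+)-(-?\d+)$", parts[2])
                if not m:
                    raise MappingError(f"{path}:{lineno}: bad residue range {parts[2]!r}")
                start, end = int(m.group(1)), int(m.group(2))
            entries.append(MappingEntry(validate_label(label), chain, start, end))
        return cls(entries, source_tag=path.stem)

    def to_file(self, path: str | Path) -> None:
        lines = [f"# subunit mapping ({self.source_tag})"]
        for e in self.entries:
            rng = f" {e.residue_start}-{e.residue_end}" if e.residue_start is not None else ""
            lines.append(f"{e.label} {e.chain_id}{rng}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class BranchModel:
    """An AtomTable partitioned into labelled subunits with roles."""

    subunits: dict[str, AtomTable]
    provenance: str = ""
    unmapped_chains: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return list(self.subunits)

    def labels_with_role(self, role: str) -> list[str]:
        return [l for l in self.subunits if role_of(l) == role]

    def role_counts(self) -> dict[str, int]:
        counts = {"mother": 0, "daughter": 0, "complex": 0}
        for label in self.subunits:
            counts[role_of(label)] += 1
        return counts

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    def atom_table(self, labels: Iterable[str] | None = None) -> AtomTable:
        """Concatenated table of the requested subunits, with a ``label`` column."""
        labels = list(self.subunits) if labels is None else list(labels)
        frames = []
        for label in labels:
            if label not in self.subunits:
                raise KeyError(f"no subunit {label!r} in model")
            df = self.subunits[label].df.copy()
            df["label"] = label
            frames.append(df)
        return AtomTable(pd.concat(frames, ignore_index=True))

    def transformed(self, fn: Callable[[np.ndarray], np.ndarray]) -> "BranchModel":
        """New model with ``fn`` applied to every subunit's coordinates."""
        subs = {
            lab: tab.with_coords(fn(tab.coords)) for lab, tab in self.subunits.items()
        }
        return BranchModel(subs, provenance=self.provenance, unmapped_chains=list(self.unmapped_chains))


def assign_subunits(atoms: AtomTable, mapping: SubunitMapping) -> BranchModel:
    """Partition polymer atoms into labelled subunits.

    Every atom matched by a mapping entry is assigned exactly once (the
    mapping's disjointness invariant guarantees this).  Chains present in the
    structure but absent from the mapping are reported in
    ``model.unmapped_chains`` and excluded.  Referencing a chain the structure
    does not contain raises :class:`MissingChainError`.
    """
    poly = atoms.polymer()
    present = set(poly.df["chain_id"])
    missing = [e.chain_id for e in mapping.entries if e.chain_id not in present]
    if missing:
        raise MissingChainError(
            f"mapping references chains absent from structure: {sorted(set(missing))}"
        )
    subunits: dict[str, AtomTable] = {}
    assigned_index: list[pd.Index] = []
    for e in mapping.entries:
        df = poly.df[poly.df["chain_id"] == e.chain_id]
        if e.residue_start is not None or e.residue_end is not None:
            df = df[df["residue_number"].map(e.covers)]
        subunits[validate_label(e.label)] = AtomTable(df.copy())
        assigned_index.append(df.index)
    mapped_chains = {e.chain_id for e in mapping.entries}
    unmapped = sorted(present - mapped_chains)
    model = BranchModel(
        subunits,
        provenance=mapping.source_tag,
        unmapped_chains=unmapped,
    )
    return model


def select_atoms(
    model: BranchModel,
    labels: Sequence[str],
    atom_name: str | None = "CA",
    residue_filter: Callable[[int], bool] | None = None,
    require_nonempty: bool = True,
) -> AtomTable:
    """Ordered atom selection across subunits.

    Ordering is deterministic: the given label order, then residue number,
    then insertion code.  Hydrogens never carry the Calpha name, so Calpha
    selections are hydrogen-free by construction.
    """
    for label in labels:
        if label not in model.subunits:
            raise KeyError(f"no subunit {label!r} in model")
    frames = []
    for label in labels:
        df = model.subunits[label].df
        if atom_name is not None:
            df = df[df["atom_name"] == atom_name]
        if residue_filter is not None:
            df = df[df["residue_number"].map(residue_filter)]
        df = df.sort_values(
            ["residue_number", "insertion_code"], kind="mergesort"
        ).copy()
        df["label"] = label
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if require_nonempty and out.empty:
        raise EmptySelectionError(
            f"no atoms match atom_name={atom_name!r} in subunits {list(labels)}"
        )
    return AtomTable(out)


# ---------------------------------------------------------------------------
# PDB writing (synthetic models and round-trips)

_CHAIN_POOL = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def default_chain_assignment(labels: Sequence[str]) -> dict[str, str]:
    """Stable label -> single-character chain id assignment for PDB output."""
    if len(labels) > len(_CHAIN_POOL):
        raise ValueError("too many subunits for single-character PDB chain ids")
    return {label: _CHAIN_POOL[i] for i, label in enumerate(labels)}


def write_model_pdb(
    model: BranchModel,
    path: str | Path,
    chain_assignment: dict[str, str] | None = None,
) -> dict[str, str]:
    """Write a BranchModel as a PDB file (one chain per subunit).

    Returns the label -> chain id assignment used, so the caller can persist
    the matching mapping file with :func:`write_mapping_for`.
    """
    chains = chain_assignment or default_chain_assignment(model.labels)
    st = gemmi.Structure()
    st.name = model.provenance or "branchkit"
    gm = gemmi.Model("1")
    for label, table in model.subunits.items():
        chain = gemmi.Chain(chains[label])
        for _, row in table.df.iterrows():
            res = gemmi.Residue()
            res.name = row["residue_name"]
            res.seqid = gemmi.SeqId(int(row["residue_number"]), row["insertion_code"] or " ")
            res.het_flag = "A" if row["is_polymer"] else "H"
            atom = gemmi.Atom()
            atom.name = row["atom_name"]
            atom.element = gemmi.Element(row["element"])
            atom.pos = gemmi.Position(row["x"], row["y"], row["z"])
            atom.occ = float(row["occupancy"])
            if row["altloc"]:
                atom.altloc = row["altloc"]
            # merge consecutive atoms of the same residue
            if len(chain) and chain[-1].seqid == res.seqid and chain[-1].name == res.name:
                chain[-1].add_atom(atom)
            else:
                res.add_atom(atom)
                chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
    return chains


def write_mapping_for(
    chains: dict[str, str], path: str | Path, source_tag: str = "synthetic"
) -> SubunitMapping:
    mapping = SubunitMapping(
        [MappingEntry(label, chain) for label, chain in chains.items()],
        source_tag=source_tag,
    )
    mapping.to_file(path)
    return mapping
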