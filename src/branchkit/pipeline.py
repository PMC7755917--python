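"""Full-analysis driver: one config in, one machine-readable report out.

The report is a plain JSON-serialisable dict with a versioned schema.  Every
stage the config enables (branch angle, complex-mother and complex-daughter
contacts, buried area, anchored RMSD matrix, per-subunit RMSD against an
actin-filament reference) is run in a fixed order; stages whose optional
inputs are absent are recorded as skipped rather than silently dropped, and
per-stage errors are collected with their stage names.  Since the SASA point
set is deterministic and nothing draws random numbers, re-running the same
config reproduces the report byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .contacts import ca_contacts, contacting_subunit_summary
from .errors import BranchkitError, ConfigError
from .geometry import AxisSpec, branch_angle
from .io import BranchModel, SubunitMapping, assign_subunits, read_structure
from .sasa import buried_area
from .superpose import anchored_rmsd_matrix, rmsd_between_subunits

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Inputs and parameters for a full branch-junction analysis."""

    model_path: Path
    mapping_path: Path
    reference_model_path: Path | None = None  # second conformation (RMSD matrix)
    reference_mapping_path: Path | None = None
    actin_reference_path: Path | None = None  # filament model (per-subunit RMSD)
    actin_reference_chain: str | None = None
    actin_reference_subunits: tuple[str, ...] = ()
    cutoff: float = 10.0
    probe: float = 1.5
    n_points: int = 960
    reference_residue: int = 269
    buried_convention: str = "half_sum"
    pairing: str = "residue_number"
    run_sasa: bool = True
    strict: bool = False

    def __post_init__(self):
        for name in ("model_path", "mapping_path"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise ConfigError(f"{name} does not exist: {p}")
        for name in ("reference_model_path", "reference_mapping_path", "actin_reference_path"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise ConfigError(f"{name} does not exist: {p}")
        for name in ("cutoff", "probe"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_points < 64:
            raise ConfigError("n_points must be >= 64")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a flat key-value YAML config."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a flat key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update(overrides)
        if "actin_reference_subunits" in raw and raw["actin_reference_subunits"]:
            raw["actin_reference_subunits"] = tuple(raw["actin_reference_subunits"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_model(model_path: Path, mapping_path: Path) -> BranchModel:
    atoms = read_structure(model_path)
    mapping = SubunitMapping.from_file(mapping_path)
    return assign_subunits(atoms, mapping)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every configured stage and return the versioned report dict.

    ``report["errors"]`` collects per-stage failures; a caller wanting a
    nonzero exit on any failed stage checks its truthiness.  With
    ``config.strict`` skipped stages are treated as errors too.
    """
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "tool": "branchkit",
            "version": __version__,
            "model_sha256": _sha256(config.model_path),
            "mapping_sha256": _sha256(config.mapping_path),
            "parameters": {
                "cutoff_A": config.cutoff,
                "probe_A": config.probe,
                "n_points": config.n_points,
                "reference_residue": config.reference_residue,
                "buried_convention": config.buried_convention,
                "pairing": config.pairing,
            },
        },
        "stages": {},
        "errors": {},
        "skipped": [],
    }
    model = load_model(config.model_path, config.mapping_path)
    report["composition"] = {
        "n_subunits": model.n_subunits,
        "role_counts": model.role_counts(),
        "subunits": model.labels,
        "unmapped_chains": model.unmapped_chains,
    }
    mother = sorted(model.labels_with_role("mother"), key=lambda l: int(l[1:]))
    daughter = sorted(model.labels_with_role("daughter"), key=lambda l: int(l[1:]))
    cplx = model.labels_with_role("complex")

    def stage(name, fn, skip_reason=None):
        if skip_reason:
            report["skipped"].append({"stage": name, "reason": skip_reason})
            if config.strict:
                report["errors"][name] = f"skipped in strict mode: {skip_reason}"
            return
        try:
            report["stages"][name] = fn()
        except BranchkitError as exc:
            report["errors"][name] = str(exc)

    def _angle():
        res = branch_angle(
            model,
            AxisSpec(mother[0], mother[-1], reference_residue=config.reference_residue),
            AxisSpec(daughter[0], daughter[-1], reference_residue=config.reference_residue),
        )
        return res.to_dict()

    stage(
        "branch_angle",
        _angle,
        skip_reason=None
        if len(mother) >= 2 and len(daughter) >= 2
        else "needs >= 2 mother and >= 2 daughter subunits",
    )

    def _contacts(group_b, tag):
        def run():
            cmap = ca_contacts(model, cplx, group_b, cutoff=config.cutoff)
            summary = contacting_subunit_summary(cmap)
            out = summary.to_dict()
            out["cutoff_A"] = config.cutoff
            out["n_boundary_pairs_excluded"] = cmap.n_boundary
            return out

        return run

    stage(
        "contacts_complex_mother",
        _contacts(mother, "mother"),
        skip_reason=None if cplx and mother else "no complex or mother subunits",
    )
    stage(
        "contacts_complex_daughter",
        _contacts(daughter, "daughter"),
        skip_reason=None if cplx and daughter else "no complex or daughter subunits",
    )

    stage(
        "buried_area_complex_mother",
        lambda: buried_area(
            model,
            cplx,
            mother,
            probe=config.probe,
            convention=config.buried_convention,
            n_points=config.n_points,
        ).to_dict(),
        skip_reason=None
        if (config.run_sasa and cplx and mother)
        else ("SASA disabled" if not config.run_sasa else "no complex or mother subunits"),
    )

    def _rmsd_matrix():
        ref = load_model(config.reference_model_path, config.reference_mapping_path)
        labels = [l for l in cplx if l in ref.subunits]
        mat = anchored_rmsd_matrix(model, ref, labels, pairing=config.pairing)
        return mat.to_dict()

    stage(
        "rmsd_matrix",
        _rmsd_matrix,
        skip_reason=None
        if config.reference_model_path and config.reference_mapping_path
        else "no reference model configured",
    )

    def _rmsd_vs_reference():
        atoms = read_structure(config.actin_reference_path)
        chain = config.actin_reference_chain or atoms.polymer().chain_ids[0]
        ref_sub = atoms.polymer().select(chain_id=chain)
        subunits = list(config.actin_reference_subunits) or mother
        out = {}
        for label in subunits:
            rmsd, n = rmsd_between_subunits(
                model, label, ref_sub, pairing="sequence_alignment"
            )
            out[label] = {"rmsd_A": rmsd, "n_pairs": n}
        out["reference_chain"] = chain
        return out

    stage(
        "rmsd_vs_actin_reference",
        _rmsd_vs_reference,
        skip_reason=None
        if config.actin_reference_path
        else "no actin reference configured",
    )
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
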