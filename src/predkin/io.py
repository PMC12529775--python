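"""Readers and writers for the package's plain-text formats.

Formats
-------
Multi-frame XYZ
    Standard layout (atom count line, comment line, one ``El x y z`` line
    per atom).  The comment line may carry ``energy=<value>
    unit=<hartree|kcalmol>``; energies are converted to kcal/mol on read.

Hessian file
    A header line ``# unit=hartree_bohr2`` or ``# unit=kcalmol_ang2``
    followed by the full 3N x 3N matrix, whitespace-delimited, row-major.

Ensemble manifest (CSV)
    Columns ``id, role, medium, solvent, xyz_file, frame_index,
    hessian_file, energy, energy_unit, symmetry_number, n_imag_expected``;
    file paths are relative to the manifest's directory.

PES grid
    Header lines ``# phi1: <first> <spacing> <n> periodic=<0|1>`` (same
    for phi2) and ``# unit=kcalmol``, then the energy matrix with phi1 as
    the row axis.

Atom indices in manifests and on the command line are 1-based (chemistry
convention) and converted to 0-based internally.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import (
    BODY_TEMPERATURE_K,
    CODATA2018,
    DEFAULT_FREQUENCY_SCALE,
)
from .conformers import Conformer, ConformerEnsemble
from .errors import ManifestError
from .torsion import PESGrid

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_hessian",
    "write_hessian",
    "read_ensemble",
    "write_ensemble",
    "read_pes_grid",
    "write_pes_grid",
    "RunConfig",
]

_ATOM_MASSES = {
    "H": 1.008, "He": 4.0026, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "Cl": 35.45,
}

MANIFEST_COLUMNS = [
    "id", "role", "medium", "solvent", "xyz_file", "frame_index",
    "hessian_file", "energy", "energy_unit", "symmetry_number",
    "n_imag_expected",
]


def _parse_comment(comment: str) -> dict:
    meta = {}
    for token in comment.split():
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


def read_xyz(path) -> list[tuple[tuple[str, ...], np.ndarray, dict]]:
    """Read a multi-frame XYZ file.

    Returns a list of (elements, Nx3 coordinates, metadata) per frame;
    metadata holds any ``key=value`` tokens from the comment line, with
    ``energy`` converted to kcal/mol when a unit tag is present.
    """
    lines = Path(path).read_text().splitlines()
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ManifestError(f"{path}: bad atom-count line {pos + 1}") from exc
        if pos + 1 + n >= len(lines) + 1:
            raise ManifestError(f"{path}: truncated frame at line {pos + 1}")
        meta = _parse_comment(lines[pos + 1])
        elements, coords = [], []
        for row in lines[pos + 2 : pos + 2 + n]:
            parts = row.split()
            if len(parts) < 4:
                raise ManifestError(f"{path}: malformed atom line {row!r}")
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        if "energy" in meta:
            unit = meta.get("unit", "kcalmol")
            energy = float(meta["energy"])
            if unit == "hartree":
                energy *= CODATA2018.hartree_to_kcalmol
            elif unit != "kcalmol":
                raise ManifestError(f"{path}: unknown energy unit {unit!r}")
            meta["energy"] = energy
        frames.append((tuple(elements), np.array(coords), meta))
        pos += 2 + n
    if not frames:
        raise ManifestError(f"{path}: no frames found")
    return frames


def write_xyz(path, frames, comments: list[str] | None = None) -> None:
    """Write (elements, coordinates) frames to a multi-frame XYZ file."""
    out = []
    for k, (elements, coords) in enumerate(frames):
        out.append(str(len(elements)))
        out.append(comments[k] if comments else "")
        for el, (x, y, z) in zip(elements, np.asarray(coords, float)):
            out.append(f"{el:2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_hessian(path) -> np.ndarray:
    """Read a plain-text Hessian; returns kcal mol^-1 A^-2."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ManifestError(f"{path}: missing '# unit=...' header")
    unit = _parse_comment(lines[0].lstrip("# ")).get("unit")
    matrix = np.loadtxt(lines[1:])
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ManifestError(f"{path}: Hessian must be square, got {matrix.shape}")
    if unit == "hartree_bohr2":
        matrix = matrix * CODATA2018.hartree_bohr2_to_kcalmol_ang2
    elif unit != "kcalmol_ang2":
        raise ManifestError(f"{path}: unknown Hessian unit {unit!r}")
    return matrix


def write_hessian(path, hessian: np.ndarray, unit: str = "kcalmol_ang2") -> None:
    if unit != "kcalmol_ang2":
        raise ValueError("Hessians are written in kcalmol_ang2")
    header = "# unit=kcalmol_ang2"
    np.savetxt(path, np.asarray(hessian, float), header=header, comments="",
               fmt="%.12e")


def _masses_for(elements) -> np.ndarray:
    try:
        return np.array([_ATOM_MASSES[e] for e in elements])
    except KeyError as exc:
        raise ManifestError(f"no mass tabulated for element {exc}") from exc


def read_ensemble(
    manifest_path,
    role: str | None = None,
    medium: str | None = None,
    validate: bool = True,
) -> ConformerEnsemble:
    """Load a conformer ensemble from a manifest CSV.

    Rows can be filtered by ``role`` / ``medium``; the selected rows must
    be homogeneous in both.  Energies are converted to kcal/mol and
    referenced to the most stable member on load; validation failures name
    the offending manifest row.  With ``validate`` (default) each
    conformer's Hessian is diagonalized on load and its imaginary-mode
    count checked against the declared stationary-point type.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ManifestError(f"{manifest_path}: missing columns {sorted(missing)}")
    if role is not None:
        table = table[table["role"] == role]
    if medium is not None:
        table = table[table["medium"] == medium]
    if table.empty:
        raise ManifestError(f"{manifest_path}: no rows match the selection")
    conformers = []
    xyz_cache: dict[str, list] = {}
    for row_number, row in table.iterrows():
        where = f"{manifest_path} row {row_number + 2}"  # header + 1-based
        xyz_file = str(base / row["xyz_file"])
        if xyz_file not in xyz_cache:
            xyz_cache[xyz_file] = read_xyz(xyz_file)
        try:
            elements, coords, _ = xyz_cache[xyz_file][int(row["frame_index"])]
        except IndexError as exc:
            raise ManifestError(f"{where}: frame_index out of range") from exc
        hessian = None
        if isinstance(row["hessian_file"], str) and row["hessian_file"]:
            hessian = read_hessian(base / row["hessian_file"])
            if hessian.shape[0] != 3 * len(elements):
                raise ManifestError(
                    f"{where}: Hessian dimension {hessian.shape[0]} != 3N = "
                    f"{3 * len(elements)}"
                )
        energy = float(row["energy"])
        unit = str(row["energy_unit"])
        if unit == "hartree":
            energy *= CODATA2018.hartree_to_kcalmol
        elif unit != "kcalmol":
            raise ManifestError(f"{where}: unknown energy unit {unit!r}")
        try:
            conformer = Conformer(
                id=str(row["id"]),
                elements=elements,
                geometry=coords,
                masses=_masses_for(elements),
                energy=energy,
                hessian=hessian,
                n_imag_expected=int(row["n_imag_expected"]),
                symmetry_number=int(row["symmetry_number"]),
            )
        except ValueError as exc:
            raise ManifestError(f"{where}: {exc}") from exc
        if validate and hessian is not None:
            from .errors import StationaryPointError
            from .partition import harmonic_frequencies

            try:
                harmonic_frequencies(conformer, scale_factor=1.0)
            except StationaryPointError as exc:
                raise StationaryPointError(f"{where}: {exc}") from exc
        conformers.append(conformer)
    roles = set(table["role"])
    media = set(table["medium"])
    solvents = set(table["solvent"])
    if len(roles) > 1 or len(media) > 1:
        raise ManifestError(
            f"{manifest_path}: mixed roles/media in one ensemble: {roles}, {media}"
        )
    return ConformerEnsemble(
        conformers=conformers,
        role=roles.pop(),
        medium=media.pop(),
        solvent=solvents.pop() if len(solvents) == 1 else "gas",
    )


def write_ensemble(ensemble: ConformerEnsemble, directory, stem: str = "ensemble"):
    """Write an ensemble as manifest + XYZ + Hessian files.

    Returns the manifest path.  Conformer energies are written in kcal/mol
    relative to the ensemble minimum (the absolute reference is carried in
    the ``energy`` column by adding ``reference_energy`` back).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    xyz_path = directory / f"{stem}.xyz"
    frames = [(c.elements, c.geometry) for c in ensemble]
    comments = [
        f"id={c.id} energy={c.energy + ensemble.reference_energy:.10f} unit=kcalmol"
        for c in ensemble
    ]
    write_xyz(xyz_path, frames, comments)
    rows = []
    for k, c in enumerate(ensemble):
        hessian_file = ""
        if c.hessian is not None:
            hessian_file = f"{stem}_{c.id}.hess"
            write_hessian(directory / hessian_file, c.hessian)
        rows.append(
            {
                "id": c.id,
                "role": ensemble.role,
                "medium": ensemble.medium,
                "solvent": ensemble.solvent,
                "xyz_file": xyz_path.name,
                "frame_index": k,
                "hessian_file": hessian_file,
                "energy": c.energy + ensemble.reference_energy,
                "energy_unit": "kcalmol",
                "symmetry_number": c.symmetry_number,
                "n_imag_expected": c.n_imag_expected,
            }
        )
    manifest = directory / f"{stem}_manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def write_pes_grid(path, grid: PESGrid) -> None:
    d1 = float(grid.phi1[1] - grid.phi1[0])
    d2 = float(grid.phi2[1] - grid.phi2[0])
    header = (
        f"# phi1: {grid.phi1[0]} {d1} {len(grid.phi1)} periodic={int(grid.periodic[0])}\n"
        f"# phi2: {grid.phi2[0]} {d2} {len(grid.phi2)} periodic={int(grid.periodic[1])}\n"
        "# unit=kcalmol"
    )
    np.savetxt(path, grid.values, header=header, comments="", fmt="%.8e")


def read_pes_grid(path) -> PESGrid:
    lines = Path(path).read_text().splitlines()
    axes = {}
    periodic = {}
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if line.startswith("# phi"):
            name, _, rest = line.lstrip("# ").partition(":")
            first, spacing, count, per = rest.split()
            axes[name] = np.arange(int(count)) * float(spacing) + float(first)
            periodic[name] = per.split("=")[1] == "1"
    if set(axes) != {"phi1", "phi2"}:
        raise ManifestError(f"{path}: missing phi1/phi2 axis headers")
    values = np.loadtxt(lines[body_start:])
    return PESGrid(
        values, axes["phi1"], axes["phi2"], (periodic["phi1"], periodic["phi2"])
    )


@dataclass
class RunConfig:
    """Run settings; defaults reproduce the study conditions (37 C, scaled
    MPWB1K frequencies, ZPE-corrected conformer weights)."""

    temperature: float = BODY_TEMPERATURE_K
    frequency_scale: float = DEFAULT_FREQUENCY_SCALE
    zpe_in_weights: bool = True
    histogram_bins: int = 72
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.frequency_scale <= 0:
            raise ValueError("temperature and frequency scale must be positive")
        if self.histogram_bins < 4:
            raise ValueError("need at least 4 histogram bins")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ManifestError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def as_dict(self) -> dict:
        return asdict(self)
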