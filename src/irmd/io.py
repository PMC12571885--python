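"""File I/O: extended-XYZ geometries/datasets and two-column spectra.

The extended-XYZ dialect written here is
``Properties=species:S:1:pos:R:3[:vel:R:3][:forces:R:3]`` with optional
``energy=...`` and ``dipole="dx dy dz"`` entries in the comment line — the
de-facto standard consumed by common atomistic tooling.  Floats are written
with 17 significant digits so write→read→write is idempotent byte-for-byte
and round-trips positions and labels exactly.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

from .core import Geometry, LabeledSample, Spectrum, StructuralError, Trajectory

PathLike = Union[str, Path]

_FLOAT_FMT = "%.16e"


class ExtXYZParseError(ValueError):
    """Malformed extended-XYZ input; message names the offending line."""


def _split_comment(comment: str) -> dict:
    """Parse key=value tokens, honouring double-quoted values."""
    out = {}
    for m in re.finditer(r'(\S+?)=(?:"([^"]*)"|(\S+))', comment):
        key, quoted, bare = m.groups()
        out[key] = quoted if quoted is not None else bare
    return out


def read_extxyz(path: PathLike) -> List[LabeledSample]:
    """Read an extended-XYZ file into labelled samples.

    Missing labels (energy, forces, dipole, velocities) come back as
    ``None``, never as zeros.
    """
    lines = Path(path).read_text().splitlines()
    samples: List[LabeledSample] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise ExtXYZParseError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if n_atoms <= 0:
            raise ExtXYZParseError(f"line {i + 1}: non-positive atom count")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        fields = _split_comment(comment)
        props = fields.get("Properties", "species:S:1:pos:R:3")
        cols = props.split(":")
        if len(cols) % 3 != 0:
            raise ExtXYZParseError(f"line {i + 2}: malformed Properties={props!r}")
        layout = [(cols[j], int(cols[j + 2])) for j in range(0, len(cols), 3)]
        expected_cols = sum(w for _, w in layout)

        symbols: list[str] = []
        rows: list[list[float]] = []
        for k in range(n_atoms):
            ln_idx = i + 2 + k
            if ln_idx >= len(lines) or not lines[ln_idx].strip():
                raise StructuralError(
                    f"line {i + 1}: frame declares {n_atoms} atoms but only "
                    f"{k} atom lines found"
                )
            parts = lines[ln_idx].split()
            if len(parts) != expected_cols:
                raise ExtXYZParseError(
                    f"line {ln_idx + 1}: expected {expected_cols} columns, "
                    f"got {len(parts)}"
                )
            symbols.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ExtXYZParseError(f"line {ln_idx + 1}: non-numeric field") from exc

        data = np.array(rows, dtype=float) if rows else np.zeros((0, 0))
        offset = 0
        arrays = {}
        for name, width in layout:
            if name == "species":
                continue
            arrays[name] = data[:, offset : offset + width]
            offset += width

        positions = arrays.get("pos")
        if positions is None:
            raise ExtXYZParseError(f"line {i + 2}: Properties lacks a pos field")
        geom = Geometry(tuple(symbols), positions, velocities=arrays.get("vel"))

        energy = float(fields["energy"]) if "energy" in fields else None
        dipole = (
            np.array([float(x) for x in fields["dipole"].split()])
            if "dipole" in fields
            else None
        )
        samples.append(
            LabeledSample(geom, energy=energy, forces=arrays.get("forces"), dipole=dipole)
        )
        i += 2 + n_atoms
    if not samples:
        raise ExtXYZParseError("file contains no frames")
    return samples


def write_extxyz(samples: Sequence[LabeledSample], path: PathLike) -> None:
    """Write labelled samples as extended-XYZ; refuses an empty list."""
    if len(samples) == 0:
        raise ValueError("refusing to write an empty extended-XYZ file")
    chunks = []
    for s in samples:
        g = s.geometry
        props = "species:S:1:pos:R:3"
        blocks = [g.positions]
        if g.velocities is not None:
            props += ":vel:R:3"
            blocks.append(g.velocities)
        if s.forces is not None:
            props += ":forces:R:3"
            blocks.append(s.forces)
        comment = [f"Properties={props}"]
        if s.energy is not None:
            comment.append("energy=" + _FLOAT_FMT % s.energy)
        if s.dipole is not None:
            comment.append(
                'dipole="' + " ".join(_FLOAT_FMT % x for x in s.dipole) + '"'
            )
        chunks.append(str(g.n_atoms))
        chunks.append(" ".join(comment))
        table = np.hstack(blocks)
        for sym, row in zip(g.symbols, table):
            chunks.append(sym + " " + " ".join(_FLOAT_FMT % x for x in row))
    Path(path).write_text("\n".join(chunks) + "\n")


def trajectory_to_samples(traj: Trajectory) -> List[LabeledSample]:
    """View a trajectory as labelled samples (per-frame dipole/energy carried over)."""
    out = []
    for i, frame in enumerate(traj.frames):
        out.append(
            LabeledSample(
                frame,
                energy=None if traj.energies is None else float(traj.energies[i]),
                dipole=None if traj.dipoles is None else traj.dipoles[i],
            )
        )
    return out


def write_trajectory(traj: Trajectory, path: PathLike) -> None:
    write_extxyz(trajectory_to_samples(traj), path)


def read_trajectory(path: PathLike, dt: float) -> Trajectory:
    """Read an extended-XYZ trajectory recorded at interval ``dt`` (fs)."""
    samples = read_extxyz(path)
    dipoles = None
    if all(s.dipole is not None for s in samples):
        dipoles = np.array([s.dipole for s in samples])
    energies = None
    if all(s.energy is not None for s in samples):
        energies = np.array([s.energy for s in samples])
    return Trajectory(
        [s.geometry for s in samples], dt=dt, dipoles=dipoles, energies=energies
    )


def read_spectrum(path: PathLike) -> Spectrum:
    """Read a two-column (wavenumber cm⁻¹, intensity) text spectrum.

    Comment lines starting with ``#``, ``;`` or ``%`` are skipped.
    Descending files are reversed; duplicate wavenumbers are rejected.
    """
    rows = []
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped[0] in "#;%":
            continue
        parts = stripped.split()
        if len(parts) < 2:
            raise ValueError(f"line {ln_no}: expected two columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ValueError(f"line {ln_no}: non-numeric value") from exc
    if len(rows) < 2:
        raise ValueError("spectrum needs at least 2 points")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        raise ValueError("duplicate wavenumbers in spectrum")
    return Spectrum(arr[:, 0], arr[:, 1])


def write_spectrum(
    spectrum: Spectrum,
    path: PathLike,
    std: Optional[np.ndarray] = None,
    stick: bool = False,
) -> None:
    """Write a spectrum as two-column text (optional third column: std or
    a 'stick' flag for discrete line spectra)."""
    lines = ["# wavenumber_cm-1 intensity" + (" std" if std is not None else "")]
    for i in range(spectrum.n_points):
        row = f"{spectrum.wavenumbers[i]:.8f} {spectrum.intensities[i]:.10e}"
        if std is not None:
            row += f" {std[i]:.10e}"
        elif stick:
            row += " stick"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")
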