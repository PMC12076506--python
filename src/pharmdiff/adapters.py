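"""Adapters for external validity and docking tools.

Pose validity checking and docking scoring are delegated to external
executables through file exchange; neither is re-implemented.  Offline stubs
let the pipeline run end-to-end without the tools, and every stubbed result
is labeled as such so downstream reports never present placeholder numbers
as computed ones.
"""

from __future__ import annotations

import csv
import shutil
import subprocess
from pathlib import Path
from typing import Protocol, runtime_checkable

from .errors import ConfigError


class AdapterUnavailable(ConfigError):
    """The external executable backing this adapter was not found."""


@runtime_checkable
class ValidityAdapter(Protocol):
    """Contract: per-molecule plausibility booleans for an SDF vs a PDB."""

    stubbed: bool

    def assess(self, sdf_path: str | Path, pdb_path: str | Path) -> list[bool]: ...


class OfflineValidity:
    """All-pass stand-in used when no validity tool is available."""

    stubbed = True

    def assess(self, sdf_path: str | Path, pdb_path: str | Path) -> list[bool]:
        from .molio import iter_ligands
        return [True for _ in iter_ligands(sdf_path)]


class PoseBustersValidity:
    """Runs the ``bust`` command-line tool and parses its CSV verdicts."""

    stubbed = False

    def __init__(self, executable: str = "bust"):
        if shutil.which(executable) is None:
            raise AdapterUnavailable(
                f"validity executable {executable!r} not found on PATH")
        self.executable = executable

    def assess(self, sdf_path: str | Path, pdb_path: str | Path) -> list[bool]:
        result = subprocess.run(
            [self.executable, str(sdf_path), "-p", str(pdb_path),
             "--outfmt", "csv"],
            capture_output=True, text=True, check=True)
        rows = list(csv.DictReader(result.stdout.splitlines()))
        verdict_cols = [c for c in (rows[0] if rows else {})
                        if c not in ("file", "molecule")]
        return [all(r[c] == "True" for c in verdict_cols) for r in rows]


@runtime_checkable
class DockingAdapter(Protocol):
    """Contract: per-molecule scores (kcal/mol, energy-minimized in-place)."""

    stubbed: bool

    def score(self, sdf_path: str | Path, pdb_path: str | Path) -> list[float]: ...


class OfflineDocking:
    """NaN-score stand-in used when no docking tool is available."""

    stubbed = True

    def score(self, sdf_path: str | Path, pdb_path: str | Path) -> list[float]:
        from .molio import iter_ligands
        return [float("nan") for _ in iter_ligands(sdf_path)]


class VinaDocking:
    """Scores poses in place (``--score_only`` / local minimization) via the
    AutoDock Vina executable."""

    stubbed = False

    def __init__(self, executable: str = "vina", minimize: bool = True):
        if shutil.which(executable) is None:
            raise AdapterUnavailable(
                f"docking executable {executable!r} not found on PATH")
        self.executable = executable
        self.minimize = minimize

    def score(self, sdf_path: str | Path, pdb_path: str | Path) -> list[float]:
        raise NotImplementedError(
            "Vina scoring requires receptor/ligand preparation (PDBQT); wire "
            "this adapter to your preparation pipeline before use")
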