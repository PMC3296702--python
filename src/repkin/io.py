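"""Readers/writers for molecule sets, field tables, and run manifests.

Molecule files are BED-like delimited text: one labeled interval per row
(``molecule_id  start_kb  end_kb  label``) with ``label`` in ``{R, G}`` and an
optional fifth column carrying the synthetic label-switch time (absent for
real data).  Header comment lines carry the lattice and provenance metadata.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .scenario import Grid, Scenario, save_scenario
from .smard import Molecule, MoleculeSet
from .solver import FieldSolution

__all__ = ["read_molecules", "write_molecules", "write_fields", "read_fields", "RunManifest", "MoleculeFormatError"]


class MoleculeFormatError(ValueError):
    """Malformed molecule file."""


def scenario_hash(scenario: Scenario) -> str:
    return hashlib.sha256(save_scenario(scenario).encode()).hexdigest()[:16]


def write_molecules(ms: MoleculeSet, path) -> None:
    """Write a molecule set as BED-like text (labels as maximal runs)."""
    path = Path(path)
    lines = [
        "# repkin molecules v1",
        f"# x0_kb={ms.x0:g} dx_kb={ms.dx:g} length_kb={ms.length:g} periodic={int(ms.periodic)}",
        f"# n_red_full={ms.n_red_full} n_green_full={ms.n_green_full} n_attempted={ms.n_attempted}",
    ]
    if ms.t_window is not None:
        lines.append(f"# t_window_sec={ms.t_window:g}")
    if ms.seed is not None:
        lines.append(f"# seed={ms.seed}")
    if ms.fragment is not None:
        lines.append(f"# fragment={ms.fragment[0]:g}:{ms.fragment[1]:g}")
    lines.append("# columns: molecule_id start_kb end_kb label [t_switch_sec]")
    for m in ms.molecules:
        lab = m.label
        edges = np.nonzero(np.diff(lab.astype(np.int8)) != 0)[0] + 1
        starts = np.concatenate([[0], edges])
        stops = np.concatenate([edges, [len(lab)]])
        for s, e in zip(starts, stops):
            row = [
                m.id,
                f"{ms.x0 + s * ms.dx:.4f}",
                f"{ms.x0 + e * ms.dx:.4f}",
                "R" if lab[s] else "G",
            ]
            if m.t_switch is not None:
                row.append(f"{m.t_switch:.3f}")
            lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_molecules(path) -> MoleculeSet:
    """Read a BED-like molecule file; validates coverage and overlap."""
    path = Path(path)
    meta: Dict[str, str] = {}
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) not in (4, 5):
            raise MoleculeFormatError(f"{path}:{lineno}: expected 4 or 5 columns, got {len(parts)}")
        mid, s, e, lab = parts[:4]
        if lab not in ("R", "G"):
            raise MoleculeFormatError(f"{path}:{lineno}: label must be R or G, got {lab!r}")
        try:
            s, e = float(s), float(e)
        except ValueError as exc:
            raise MoleculeFormatError(f"{path}:{lineno}: non-numeric interval") from exc
        if e <= s:
            raise MoleculeFormatError(f"{path}:{lineno}: empty or inverted interval")
        tsw = float(parts[4]) if len(parts) == 5 else None
        rows.append((mid, s, e, lab, tsw))
    if not rows:
        raise MoleculeFormatError(f"{path}: no molecule rows")

    x0 = float(meta.get("x0_kb", min(r[1] for r in rows)))
    dx = float(meta.get("dx_kb", 0.1))
    length = float(meta.get("length_kb", max(r[2] for r in rows) - x0))
    n_sites = int(round(length / dx))

    mols: List[Molecule] = []
    by_id: Dict[str, list] = {}
    order: List[str] = []
    for r in rows:
        if r[0] not in by_id:
            order.append(r[0])
        by_id.setdefault(r[0], []).append(r)
    for mid in order:
        ivals = sorted(by_id[mid], key=lambda r: r[1])
        label = np.zeros(n_sites, dtype=np.uint8)
        covered = np.zeros(n_sites, dtype=bool)
        tsw = None
        for _, s, e, lab, t in ivals:
            i0 = int(round((s - x0) / dx))
            i1 = int(round((e - x0) / dx))
            if i0 < 0 or i1 > n_sites:
                raise MoleculeFormatError(f"molecule {mid}: interval [{s}, {e}] outside declared extent")
            if covered[i0:i1].any():
                raise MoleculeFormatError(f"molecule {mid}: overlapping intervals")
            covered[i0:i1] = True
            label[i0:i1] = 1 if lab == "R" else 0
            if t is not None:
                tsw = t
        if not covered.all():
            raise MoleculeFormatError(f"molecule {mid}: gaps in coverage")
        mols.append(Molecule(id=mid, x0=x0, dx=dx, label=label, t_switch=tsw))
    frag = None
    if "fragment" in meta:
        a, b = meta["fragment"].split(":")
        frag = (float(a), float(b))
    return MoleculeSet(
        molecules=mols,
        x0=x0,
        dx=dx,
        length=length,
        periodic=bool(int(meta.get("periodic", 0))),
        n_red_full=int(meta.get("n_red_full", 0)),
        n_green_full=int(meta.get("n_green_full", 0)),
        n_attempted=int(meta.get("n_attempted", 0)),
        t_window=float(meta["t_window_sec"]) if "t_window_sec" in meta else None,
        seed=int(meta["seed"]) if "seed" in meta else None,
        fragment=frag,
    )


def write_fields(sol: FieldSolution, outdir) -> None:
    """Write solution fields as TSV tables (one per field) with grid headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = (
        f"# repkin fields v1; units: x kb, t sec, f dimensionless, rho forks/kb\n"
        f"# x0={sol.grid.x0:g} dx={sol.grid.dx:g} length={sol.grid.length:g} "
        f"dt={sol.grid.dt:g} t_max={sol.grid.t_max:g}\n"
    )
    fields = {"f": sol.f, "rho_plus": sol.rho_plus, "rho_minus": sol.rho_minus,
              "f_plus": sol.f_plus, "f_minus": sol.f_minus}
    if sol.has_stalls:
        fields["rho_stall_plus"] = sol.rho_stall_plus
        fields["rho_stall_minus"] = sol.rho_stall_minus
    for name, arr in fields.items():
        df = pd.DataFrame(arr, index=pd.Index(sol.t, name="t_sec"),
                          columns=[f"{x:.4f}" for x in sol.x])
        with open(outdir / f"{name}.tsv", "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t")


def read_fields(outdir) -> Dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    out = {}
    for p in sorted(outdir.glob("*.tsv")):
        out[p.stem] = pd.read_csv(p, sep="\t", comment="#", index_col=0)
    return out


@dataclass
class RunManifest:
    """Provenance record written next to every stochastic output."""

    command: str
    config_hash: str
    seed: Optional[int]
    version: str = _pkg_version
    grid: Optional[dict] = None
    inputs: List[str] = field(default_factory=list)
    outputs: List[str] = field(default_factory=list)
    wall_time_sec: float = 0.0

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        p = outdir / "manifest.json"
        p.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return p

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
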