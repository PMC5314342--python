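"""Readers and writers for the pipeline's text formats.

PDB ingestion goes through Biopython; coordinates are converted from
Angstrom to nm on the way in.  Trajectories are written as XYZ with a
self-describing comment line; CV series as COLVAR-style whitespace text
with a "#! FIELDS" header; hills and free-energy grids in matching text
dialects.  All writers are deterministic byte-for-byte: fixed precision,
fixed column order, no timestamps.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import ANGSTROM_PER_NM
from .core import Conformation, Trajectory
from .cvs import CVRecord
from .metad import FESGrid, Hill

__all__ = [
    "PdbModel",
    "read_pdb",
    "map_to_coarse",
    "read_fasta_sequence",
    "write_xyz",
    "read_xyz",
    "write_colvar",
    "read_colvar",
    "write_hills",
    "read_hills",
    "write_fes",
]

_FMT = "%.6f"


@dataclass
class PdbModel:
    """One MODEL block of a PDB file, coordinates already in nm."""

    serials: np.ndarray
    names: list[str]
    resnames: list[str]
    chains: list[str]
    resseqs: np.ndarray
    coords: np.ndarray  # (n_atoms, 3), nm
    elements: list[str]

    @property
    def n_atoms(self) -> int:
        return len(self.names)


def read_pdb(path) -> list[PdbModel]:
    """Parse a PDB file into one PdbModel per MODEL block (Angstrom
    converted to nm)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("m", str(path))
    models = []
    for model in structure:
        serials, names, resnames, chains, resseqs, xyz, elements = \
            [], [], [], [], [], [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    serials.append(atom.serial_number or 0)
                    names.append(atom.get_name())
                    resnames.append(res.get_resname().strip())
                    chains.append(chain.id)
                    resseqs.append(res.id[1])
                    xyz.append(atom.coord / ANGSTROM_PER_NM)
                    elements.append(atom.element or "")
        models.append(PdbModel(
            serials=np.asarray(serials, dtype=int), names=names,
            resnames=resnames, chains=chains,
            resseqs=np.asarray(resseqs, dtype=int),
            coords=np.asarray(xyz, dtype=float), elements=elements))
    if not models:
        raise ValueError(f"no models found in {path}")
    return models


def map_to_coarse(model: PdbModel, mapping: dict, chain: str | None = None
                  ) -> Conformation:
    """Map an atomistic model onto the four-site coarse representation.

    ``mapping`` gives per-residue-name atom groups::

        {"RESN": {"backbone": [...names...],
                  "plane": [[...], [...], [...]]}}

    Backbone bead = mean of the backbone group; the three plane sites =
    means of the three plane groups (their centroid is the base center).
    ``chain`` restricts to one chain (strand deletion by selection).
    Raises on unmapped residues or missing plane atoms.
    """
    sel = [i for i in range(model.n_atoms)
           if chain is None or model.chains[i] == chain]
    if not sel:
        raise ValueError(f"no atoms for chain {chain!r}")
    residues: dict[tuple, dict[str, int]] = {}
    order = []
    for i in sel:
        key = (model.chains[i], int(model.resseqs[i]))
        if key not in residues:
            residues[key] = {}
            order.append(key)
        residues[key][model.names[i]] = i

    coords = []
    for key in order:
        atoms = residues[key]
        resname = model.resnames[next(iter(atoms.values()))]
        if resname not in mapping:
            raise ValueError(f"unmapped residue {resname} at {key}")
        spec = mapping[resname]

        def group_mean(names):
            idx = [atoms[n] for n in names if n in atoms]
            if not idx:
                raise ValueError(
                    f"missing atoms {names} in residue {resname} {key}")
            return model.coords[idx].mean(axis=0)

        coords.append(group_mean(spec["backbone"]))
        for g in spec["plane"]:
            coords.append(group_mean(g))
    return Conformation(np.asarray(coords))


def read_fasta_sequence(path) -> str:
    """Single-record FASTA, alphabet-checked against ACGTU."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, "
                         f"got {len(records)}")
    seq = str(records[0].seq).upper()
    bad = set(seq) - set("ACGTU")
    if bad:
        raise ValueError(f"invalid bases in FASTA: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# XYZ trajectories


def write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for k, frame in enumerate(traj.frames):
            fh.write(f"{frame.n_sites}\n")
            fh.write(f"time_ps={k * traj.dt:.6f} "
                     f"temperature_K={traj.temperature:.6f} "
                     f"seed={traj.seed}\n")
            for x, y, z in frame.coordinates:
                fh.write(f"X {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> Trajectory:
    frames = []
    meta = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        meta = dict(kv.split("=") for kv in lines[i + 1].split())
        block = lines[i + 2:i + 2 + n]
        if len(block) != n:
            raise ValueError("truncated XYZ frame")
        coords = np.array([[float(v) for v in ln.split()[1:4]]
                           for ln in block])
        frames.append(Conformation(coords))
        i += 2 + n
    if len(frames) < 1:
        raise ValueError("empty XYZ file")
    t_last = float(meta.get("time_ps", 0.0))
    dt = t_last / (len(frames) - 1) if len(frames) > 1 else 1.0
    return Trajectory(frames=frames, dt=dt if dt > 0 else 1.0,
                      temperature=float(meta.get("temperature_K", 0.0)),
                      seed=int(meta.get("seed", 0)))


# ---------------------------------------------------------------------------
# COLVAR


def write_colvar(records: list[CVRecord], path) -> None:
    if not records:
        raise ValueError("no records to write")
    names = list(records[0].values)
    has_bias = records[0].bias is not None
    cols = ["time", *names] + (["bias"] if has_bias else [])
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for r in records:
            if list(r.values) != names:
                raise ValueError("inconsistent CV names across records")
            vals = [r.time, *(r.values[n] for n in names)]
            if has_bias:
                vals.append(r.bias)
            fh.write(" ".join(_FMT % v for v in vals) + "\n")


def read_colvar(path) -> list[CVRecord]:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["#!", "FIELDS"]:
            raise ValueError("missing #! FIELDS header")
        cols = header[2:]
        has_bias = cols and cols[-1] == "bias"
        names = cols[1:-1] if has_bias else cols[1:]
        records = []
        for ln in fh:
            parts = [float(v) for v in ln.split()]
            if len(parts) != len(cols):
                raise ValueError("field-count mismatch in COLVAR line")
            rec = CVRecord(time=parts[0],
                           values=dict(zip(names, parts[1:1 + len(names)])),
                           bias=parts[-1] if has_bias else None)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# HILLS


def write_hills(hills: list[Hill], cv_names: list[str], biasf: float,
                path) -> None:
    cols = (["time"] + cv_names + [f"sigma_{n}" for n in cv_names]
            + ["height", "biasf"])
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for h in hills:
            vals = [h.time, *h.center, *h.sigma, h.height, biasf]
            fh.write(" ".join(_FMT % v for v in vals) + "\n")


def read_hills(path) -> tuple[list[Hill], list[str], float]:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["#!", "FIELDS"]:
            raise ValueError("missing #! FIELDS header")
        cols = header[2:]
        if cols[0] != "time" or cols[-2:] != ["height", "biasf"]:
            raise ValueError("unexpected HILLS column layout")
        d = (len(cols) - 3) // 2
        names = cols[1:1 + d]
        hills = []
        biasf = 0.0
        for ln in fh:
            parts = [float(v) for v in ln.split()]
            if len(parts) != len(cols):
                raise ValueError("field-count mismatch in HILLS line")
            biasf = parts[-1]
            hills.append(Hill(time=parts[0],
                              center=tuple(parts[1:1 + d]),
                              sigma=tuple(parts[1 + d:1 + 2 * d]),
                              height=parts[-2]))
    return hills, names, biasf


def write_fes(fes: FESGrid, path, cv_names: list[str] | None = None) -> None:
    names = cv_names or [f"cv{i}" for i in range(fes.dimension)]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names)
                 + f" free_energy\n#! UNITS {fes.units}\n")
        pts = fes.mesh().reshape(-1, fes.dimension)
        vals = fes.values.reshape(-1)
        for p, v in zip(pts, vals):
            out = " ".join(_FMT % x for x in p)
            fh.write(f"{out} " + (_FMT % v if np.isfinite(v) else "inf")
                     + "\n")
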