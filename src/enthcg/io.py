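"""File formats: two-column spectra, trajectory arrays, PDB snapshots."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .sim.system import CGSystem


def write_spectrum(path, field, amplitude,
                   header: str = "field_G amplitude") -> None:
    """Two-column whitespace-delimited spectrum with one header line."""
    data = np.column_stack([np.asarray(field, float),
                            np.asarray(amplitude, float)])
    np.savetxt(path, data, header=header, comments="# ")


def read_spectrum(path):
    """Read a two-column spectrum; returns (field, amplitude)."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns")
    return data[:, 0], data[:, 1]


def write_trajectory(path_base, frames) -> None:
    """Flat binary array plus a JSON sidecar describing the shape."""
    frames = np.asarray(frames, dtype=float)
    base = Path(path_base)
    frames.ravel().tofile(base.with_suffix(".bin"))
    base.with_suffix(".json").write_text(json.dumps(
        {"shape": list(frames.shape), "dtype": "float64",
         "order": "C", "units": "nm"}))


def read_trajectory(path_base) -> np.ndarray:
    base = Path(path_base)
    meta = json.loads(base.with_suffix(".json").read_text())
    data = np.fromfile(base.with_suffix(".bin"),
                       dtype=np.dtype(meta["dtype"]))
    return data.reshape(meta["shape"])


def write_pdb_snapshot(path, system: CGSystem,
                       bfactors=None) -> None:
    """One pseudo-atom per CG site; each lipid gets a second record at its
    head position so the director is recoverable.  Optional per-domain
    values (e.g. local order) go to the B-factor column."""
    import MDAnalysis as mda

    heads = system.head_positions()
    n_lipid_atoms = 2 * system.n_lipids
    n_prot = 16 * system.n_proteins
    n = n_lipid_atoms + n_prot
    u = mda.Universe.empty(n, trajectory=True)
    pos = np.empty((n, 3))
    pos[0:n_lipid_atoms:2] = system.lipid_pos
    pos[1:n_lipid_atoms:2] = heads
    names = ["LC", "LH"] * system.n_lipids
    tempf = np.zeros(n)
    for k, coords in enumerate(system.protein_coords):
        start = n_lipid_atoms + 16 * k
        pos[start:start + 16] = coords
        names.extend(f"C{i}" for i in range(1, 17))
        if bfactors is not None:
            tempf[start:start + 16] = bfactors[k]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("tempfactors", tempf)
    u.atoms.positions = pos * 10.0  # nm -> Angstrom for PDB
    u.atoms.write(str(path))
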