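"""Residue property tables and van der Waals radii.

Provides the nodal covariates used by the PSN ERGM terms: monoisotopic
residue mass (Da), van der Waals side-chain-inclusive residue volume (A^3),
Kyte-Doolittle hydrophobicity, formal charge at pH 7 (His treated as
neutral), a binary polar/nonpolar classification, and a distance-from-termini
score scaled to [0, 1].  Atomic van der Waals radii follow Alvarez's
consistent set.  Everything is overridable from a TSV file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResidueProperties",
    "VDW_RADII",
    "KYTE_DOOLITTLE",
    "RESIDUE_MASS",
    "RESIDUE_VOLUME",
    "RESIDUE_CHARGE",
    "NONPOLAR",
    "ABETA40_WT",
    "ABETA40_E22G",
    "termini_score",
]

# Atomic van der Waals radii (Angstrom), Alvarez consistent set.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.77,
    "N": 1.66,
    "O": 1.50,
    "S": 1.89,
    "P": 1.90,
    "F": 1.46,
    "CL": 1.82,
    "BR": 1.86,
    "I": 2.04,
}

# Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Monoisotopic residue (not free amino acid) masses, Da.
RESIDUE_MASS: dict[str, float] = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
    "C": 103.00919, "Q": 128.05858, "E": 129.04259, "G": 57.02146,
    "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
    "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
    "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}

# Residue van der Waals volumes (A^3), standard published table.
RESIDUE_VOLUME: dict[str, float] = {
    "A": 67.0, "R": 148.0, "N": 96.0, "D": 91.0, "C": 86.0,
    "Q": 114.0, "E": 109.0, "G": 48.0, "H": 118.0, "I": 124.0,
    "L": 124.0, "K": 135.0, "M": 124.0, "F": 135.0, "P": 90.0,
    "S": 73.0, "T": 93.0, "W": 163.0, "Y": 141.0, "V": 105.0,
}

# Formal side-chain charge at pH 7; His neutral.
RESIDUE_CHARGE: dict[str, int] = {aa: 0 for aa in KYTE_DOOLITTLE}
RESIDUE_CHARGE.update({"D": -1, "E": -1, "K": +1, "R": +1, "H": 0})

# Nonpolar class; everything else (charged + polar side chains) is polar.
NONPOLAR = set("AVLIPFMWGC")

# Amyloid-beta 1-40 and its Arctic (E22G) variant.
ABETA40_WT = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"
ABETA40_E22G = ABETA40_WT[:21] + "G" + ABETA40_WT[22:]


def termini_score(n: int) -> np.ndarray:
    """Distance-from-nearest-terminus score: 0 at residues 1 and n, 1 at center."""
    i = np.arange(1, n + 1)
    raw = np.minimum(i - 1, n - i).astype(float)
    return raw / raw.max()


@dataclass
class ResidueProperties:
    """Per-residue nodal covariates for a length-n chain (1-based indexing)."""

    sequence: str
    mass: np.ndarray
    volume: np.ndarray
    hydrophobicity: np.ndarray
    charge: np.ndarray
    polar: np.ndarray  # bool; True = polar class
    termini: np.ndarray

    def __post_init__(self):
        n = len(self.sequence)
        for name in ("mass", "volume", "hydrophobicity", "charge", "polar", "termini"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != sequence length {n}")
            setattr(self, name, arr)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(cls, sequence: str) -> "ResidueProperties":
        seq = sequence.upper()
        unknown = sorted(set(seq) - set(KYTE_DOOLITTLE))
        if unknown:
            raise KeyError(f"unknown residue code(s): {unknown}")
        return cls(
            sequence=seq,
            mass=np.array([RESIDUE_MASS[a] for a in seq]),
            volume=np.array([RESIDUE_VOLUME[a] for a in seq]),
            hydrophobicity=np.array([KYTE_DOOLITTLE[a] for a in seq]),
            charge=np.array([RESIDUE_CHARGE[a] for a in seq]),
            polar=np.array([a not in NONPOLAR for a in seq]),
            termini=termini_score(len(seq)),
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({
            "residue": np.arange(1, self.n_residues + 1),
            "code": list(self.sequence),
            "mass": self.mass,
            "volume": self.volume,
            "hydrophobicity": self.hydrophobicity,
            "charge": self.charge,
            "polarity": np.where(self.polar, "polar", "nonpolar"),
            "termini": self.termini,
        })
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ResidueProperties":
        df = pd.read_csv(path, sep="\t").sort_values("residue")
        return cls(
            sequence="".join(df["code"]),
            mass=df["mass"].to_numpy(float),
            volume=df["volume"].to_numpy(float),
            hydrophobicity=df["hydrophobicity"].to_numpy(float),
            charge=df["charge"].to_numpy(int),
            polar=(df["polarity"] == "polar").to_numpy(),
            termini=df["termini"].to_numpy(float),
        )


def wild_type_properties() -> ResidueProperties:
    return ResidueProperties.from_sequence(ABETA40_WT)


def arctic_properties() -> ResidueProperties:
    return ResidueProperties.from_sequence(ABETA40_E22G)
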