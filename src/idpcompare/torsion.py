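"""Backbone torsion angles, circular statistics, and sine/cosine feature encoding.

All downstream analyses (SVM affinity scoring, Markov coarse-graining) operate
on backbone dihedral angles.  Angles are radians in (-pi, pi] throughout, with
the antipodal convention that a wrapped value of exactly -pi is reported as
+pi.  Residue indexing is 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

__all__ = [
    "ConformationSet",
    "TrajectorySegment",
    "EncodedFeatures",
    "CircularMean",
    "wrap_angle",
    "circular_difference",
    "circular_mean",
    "encode_circular",
    "decode_circular",
    "angular_velocity",
    "compute_backbone_dihedrals",
    "dihedrals_from_pdb",
    "restrict_to_residues",
]


def wrap_angle(x):
    """Wrap angle(s) to (-pi, pi]; exactly antipodal values map to +pi."""
    x = np.asarray(x, dtype=float)
    w = np.mod(x + np.pi, TWO_PI) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    if w.ndim == 0:
        return float(w)
    return w


def circular_difference(from_angle, to_angle):
    """Signed minimal angular displacement from `from_angle` to `to_angle`.

    Returns a value in (-pi, pi] such that from + result == to (mod 2*pi).
    The antipodal tie (|difference| == pi) deterministically returns +pi.
    """
    return wrap_angle(np.asarray(to_angle, dtype=float) - np.asarray(from_angle, dtype=float))


@dataclass
class CircularMean:
    """Circular mean with an optional normal-approximation 95% CI."""

    mean: float
    ci_low: float | None = None
    ci_high: float | None = None
    resultant_length: float = 0.0
    defined: bool = True

    def contains(self, value: float) -> bool:
        """Whether `value` lies inside the CI, compared on the circle."""
        if self.ci_low is None:
            raise ValueError("confidence interval was not requested")
        d = circular_difference(self.mean, value)
        half = 0.5 * (self.ci_high - self.ci_low)
        return abs(d) <= half + 1e-15


def circular_mean(angles, with_ci: bool = False, level: float = 0.95) -> CircularMean:
    """Mean direction of a sample of angles.

    The mean is the argument of the mean resultant vector.  When requested,
    the CI is a normal approximation on the wrapped deviations from the mean
    (mean +/- z * circular SE), which is appropriate for the small angular
    dispersions this package deals in.  A (numerically) zero resultant length
    leaves the mean undefined and is flagged.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("circular_mean requires a non-empty sample")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    r = float(np.hypot(s, c))
    if r < 1e-12:
        return CircularMean(mean=np.nan, resultant_length=r, defined=False,
                            ci_low=np.nan if with_ci else None,
                            ci_high=np.nan if with_ci else None)
    mu = float(np.arctan2(s, c))
    if not with_ci:
        return CircularMean(mean=mu, resultant_length=r)
    dev = circular_difference(mu, a)
    n = a.size
    se = 0.0 if n < 2 else float(np.std(dev, ddof=1) / np.sqrt(n))
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    return CircularMean(mean=mu, ci_low=mu - z * se, ci_high=mu + z * se,
                        resultant_length=r)


@dataclass
class ConformationSet:
    """Labeled matrix of per-conformation backbone torsion angles.

    Parameters
    ----------
    angles
        (n_conformations, n_angles) array, radians in (-pi, pi].
    angle_labels
        Ordered (residue_index, "phi"|"psi") pairs, one per column.
    variants
        Per-row variant label (e.g. "WT", "MUT", "fibril").
    source_ids
        Optional per-row provenance identifiers.
    """

    angles: np.ndarray
    angle_labels: list[tuple[int, str]]
    variants: np.ndarray
    source_ids: np.ndarray | None = None

    def __post_init__(self):
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        self.variants = np.asarray(self.variants)
        self.angle_labels = [(int(r), str(t)) for r, t in self.angle_labels]
        if self.angles.shape[1] != len(self.angle_labels):
            raise ValueError(
                f"{self.angles.shape[1]} angle columns but "
                f"{len(self.angle_labels)} labels")
        if self.variants.shape[0] != self.angles.shape[0]:
            raise ValueError("variant labels must match row count")
        if self.angles.size and not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")
        if self.angles.size and (np.any(self.angles <= -np.pi - 1e-12)
                                 or np.any(self.angles > np.pi + 1e-12)):
            raise ValueError("angles must lie in (-pi, pi]")
        if self.source_ids is None:
            self.source_ids = np.arange(self.angles.shape[0])
        else:
            self.source_ids = np.asarray(self.source_ids)

    @property
    def n_conformations(self) -> int:
        return self.angles.shape[0]

    @property
    def n_angles(self) -> int:
        return self.angles.shape[1]

    def select_variant(self, variant) -> "ConformationSet":
        mask = self.variants == variant
        return ConformationSet(self.angles[mask], self.angle_labels,
                               self.variants[mask], self.source_ids[mask])

    @staticmethod
    def concatenate(sets: list["ConformationSet"]) -> "ConformationSet":
        first = sets[0]
        for s in sets[1:]:
            if s.angle_labels != first.angle_labels:
                raise ValueError("angle labels differ between sets")
        return ConformationSet(
            np.vstack([s.angles for s in sets]) if any(s.n_conformations for s in sets)
            else np.empty((0, first.n_angles)),
            first.angle_labels,
            np.concatenate([s.variants for s in sets]),
            np.concatenate([s.source_ids for s in sets]),
        )

    # --- TSV round-trip -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = [f"{t}_{r}" for r, t in self.angle_labels]
        df = pd.DataFrame(self.angles, columns=cols)
        df.insert(0, "variant", self.variants)
        df.insert(0, "conformation_id", self.source_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ConformationSet":
        df = pd.read_csv(path, sep="\t")
        angle_cols = [c for c in df.columns if c.startswith(("phi_", "psi_"))]
        labels = []
        for c in angle_cols:
            t, r = c.split("_")
            labels.append((int(r), t))
        return cls(df[angle_cols].to_numpy(float), labels,
                   df["variant"].to_numpy(), df["conformation_id"].to_numpy())


@dataclass
class TrajectorySegment:
    """A time-ordered ConformationSet with strictly increasing times (ps).

    `hidden_states` carries generator ground truth when available (synthetic
    trajectories); it is None for observed data.
    """

    conformations: ConformationSet
    times: np.ndarray
    hidden_states: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape[0] != self.conformations.n_conformations:
            raise ValueError("time index must match conformation count")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time index must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def uniform_spacing(self) -> bool:
        if self.times.size < 3:
            return True
        dt = np.diff(self.times)
        return bool(np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12))

    def to_tsv(self, path) -> None:
        df = self.conformations.to_frame()
        df.insert(2, "time_ps", self.times)
        if self.hidden_states is not None:
            df.insert(3, "true_basin", self.hidden_states)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrajectorySegment":
        df = pd.read_csv(path, sep="\t")
        angle_cols = [c for c in df.columns if c.startswith(("phi_", "psi_"))]
        labels = [(int(c.split("_")[1]), c.split("_")[0]) for c in angle_cols]
        conf = ConformationSet(df[angle_cols].to_numpy(float), labels,
                               df["variant"].to_numpy(),
                               df["conformation_id"].to_numpy())
        hidden = df["true_basin"].to_numpy() if "true_basin" in df else None
        return cls(conf, df["time_ps"].to_numpy(float), hidden)


@dataclass
class EncodedFeatures:
    """Sine/cosine (imaginary/real) encoding of a ConformationSet.

    Column 2j is cos of angle j, column 2j+1 is sin of angle j, in the order
    of `angle_labels` — 2 x n_angles columns total (160 for a full 40-residue
    set carrying all 80 angles).
    """

    matrix: np.ndarray
    angle_labels: list[tuple[int, str]]
    variants: np.ndarray
    source_ids: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_angles(self) -> int:
        return len(self.angle_labels)

    def column_map(self) -> list[tuple[int, str, str]]:
        """(residue, phi|psi, cos|sin) for each feature column."""
        out = []
        for r, t in self.angle_labels:
            out.append((r, t, "cos"))
            out.append((r, t, "sin"))
        return out

    def to_tsv(self, path) -> None:
        cols = [f"{t}_{r}_{c}" for r, t, c in self.column_map()]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "variant", self.variants)
        df.insert(0, "conformation_id", self.source_ids)
        df.to_csv(path, sep="\t", index=False)


def encode_circular(conformations: ConformationSet) -> EncodedFeatures:
    """Represent each torsion angle by its real (cos) and imaginary (sin) parts."""
    a = conformations.angles
    m = np.empty((a.shape[0], 2 * a.shape[1]))
    m[:, 0::2] = np.cos(a)
    m[:, 1::2] = np.sin(a)
    return EncodedFeatures(m, list(conformations.angle_labels),
                           conformations.variants.copy(),
                           conformations.source_ids.copy())


def decode_circular(features: EncodedFeatures) -> ConformationSet:
    """Invert encode_circular via atan2 (exact on the unit circle)."""
    m = features.matrix
    angles = np.arctan2(m[:, 1::2], m[:, 0::2])
    angles = wrap_angle(angles)
    return ConformationSet(angles, list(features.angle_labels),
                           features.variants.copy(), features.source_ids.copy())


def angular_velocity(burst: TrajectorySegment, per_interval: bool = False) -> np.ndarray:
    """Per-angle mean angular velocity (rad/ps) over a burst.

    Mean of circular differences between consecutive frames divided by the
    frame interval.  Requires uniform spacing unless `per_interval`, in which
    case each difference is divided by its own interval before averaging.
    """
    if burst.n_frames < 2:
        raise ValueError("angular velocity requires at least 2 frames")
    a = burst.conformations.angles
    diffs = circular_difference(a[:-1], a[1:])
    dts = np.diff(burst.times)
    if per_interval:
        return (diffs / dts[:, None]).mean(axis=0)
    if not burst.uniform_spacing:
        raise ValueError("non-uniform frame spacing; pass per_interval=True")
    return diffs.mean(axis=0) / dts[0]


# --- dihedral geometry --------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (IUPAC convention: cis = 0, trans = pi), radians in (-pi, pi]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    # projections onto the plane normal to the central bond
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return wrap_angle(np.arctan2(y, x))


def _backbone_coords(structure):
    """Extract ordered per-residue {N, CA, C} coordinate dicts.

    Accepts a Bio.PDB Chain/Model entity or any object exposing
    `backbone_atoms()` -> list of dicts keyed by atom name.
    """
    if hasattr(structure, "backbone_atoms"):
        return structure.backbone_atoms()
    # Bio.PDB entity: a Chain iterates residues; a Model iterates chains.
    try:
        from Bio.PDB.Chain import Chain
        from Bio.PDB.Model import Model
    except ImportError as exc:  # pragma: no cover
        raise ImportError("Biopython is required for PDB input") from exc
    if isinstance(structure, Model):
        chains = list(structure)
        if len(chains) != 1:
            raise ValueError(
                "model has multiple chains; pass a single chain "
                "(fibril monomers are extracted per chain)")
        structure = chains[0]
    if not isinstance(structure, Chain):
        raise TypeError(f"unsupported structure type {type(structure)!r}")
    out = []
    for res in structure:
        if res.id[0] != " ":  # skip heteroatoms/waters
            continue
        entry = {}
        for name in ("N", "CA", "C"):
            if name in res:
                entry[name] = res[name].get_coord().astype(float)
        out.append(entry)
    return out


def compute_backbone_dihedrals(structure, variant: str = "structure",
                               source_id=0) -> ConformationSet:
    """Backbone phi/psi for one structure as a single-row ConformationSet.

    phi_i is C(i-1)-N(i)-CA(i)-C(i); psi_i is N(i)-CA(i)-C(i)-N(i+1).
    Angles undefined at the chain ends (phi_1, psi_last) or next to residues
    with missing backbone atoms are omitted from the label list.
    """
    residues = _backbone_coords(structure)
    n = len(residues)
    if n < 2:
        raise ValueError("need at least 2 residues to define a dihedral")
    labels: list[tuple[int, str]] = []
    values: list[float] = []
    for i in range(n):  # 0-based here; labels are 1-based
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i < n - 1 else None
        cur = residues[i]
        has_cur = all(k in cur for k in ("N", "CA", "C"))
        if prev_res is not None and "C" in prev_res and has_cur:
            labels.append((i + 1, "phi"))
            values.append(dihedral_angle(prev_res["C"], cur["N"], cur["CA"], cur["C"]))
        if next_res is not None and "N" in next_res and has_cur:
            labels.append((i + 1, "psi"))
            values.append(dihedral_angle(cur["N"], cur["CA"], cur["C"], next_res["N"]))
    # reorder: all phi then interleaved by residue is unconventional; keep
    # residue-major ordering (phi_i, psi_i) as produced above.
    return ConformationSet(np.array([values]), labels,
                           np.array([variant]), np.array([source_id]))


def dihedrals_from_pdb(path, variant: str = "pdb", all_models: bool = False,
                       quiet: bool = True) -> ConformationSet:
    """Torsion angles for every monomer chain of a PDB file.

    By default only the first model of a multi-model file is read; with
    `all_models` every model contributes (fibril NMR bundles are multi-model,
    multi-chain — each chain of each model is one conformation row).  Rows
    whose chains yield differing angle label sets are aligned on the common
    labels.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=quiet)
    struct = parser.get_structure("s", str(path))
    models = list(struct) if all_models else [next(iter(struct))]
    rows = []
    for mi, model in enumerate(models):
        for chain in model:
            try:
                cs = compute_backbone_dihedrals(
                    chain, variant=variant,
                    source_id=f"{Path(path).stem}:m{mi}:{chain.id}")
            except ValueError:
                continue
            rows.append(cs)
    if not rows:
        raise ValueError(f"no usable chains in {path}")
    common = [lab for lab in rows[0].angle_labels
              if all(lab in r.angle_labels for r in rows)]
    aligned = []
    for r in rows:
        idx = [r.angle_labels.index(lab) for lab in common]
        aligned.append(ConformationSet(r.angles[:, idx], common,
                                       r.variants, r.source_ids))
    return ConformationSet.concatenate(aligned)


def restrict_to_residues(conformations: ConformationSet,
                         residue_range: tuple[int, int]) -> ConformationSet:
    """Keep only angle columns whose residue index lies in [lo, hi] (inclusive)."""
    lo, hi = residue_range
    keep = [j for j, (r, _) in enumerate(conformations.angle_labels)
            if lo <= r <= hi]
    if not keep:
        raise ValueError(f"no angles with residue index in [{lo}, {hi}]")
    return ConformationSet(conformations.angles[:, keep],
                           [conformations.angle_labels[j] for j in keep],
                           conformations.variants, conformations.source_ids)
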