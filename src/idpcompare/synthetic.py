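"""Synthetic study-condition generators.

Every input the analysis pipeline would normally obtain from molecular
dynamics is emulated here with known ground truth: variant conformation
ensembles drawn from shared von Mises basin mixtures with small site-specific
angle shifts, long Markov-switching trajectories over those basins with
variant-specific transition matrices, fibril-like conformation sets
concentrated on a reference geometry, toy sphere-per-residue coordinate
structures realizing prescribed contact maps, and ERGM-sampled PSN ensembles.

The two variants share their basin structure; they differ only through the
injected angle shifts and their basin-transition kinetics, emulating systems
whose marginal (Ramachandran) distributions are near-identical while their
dynamics differ.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .ergm import ErgmModel, simulate_ergm
from .properties import ResidueProperties, VDW_RADII
from .torsion import ConformationSet, TrajectorySegment, wrap_angle

__all__ = [
    "SyntheticSpec",
    "ToyStructure",
    "two_variant_spec",
    "sample_conformations",
    "simulate_trajectory",
    "sample_fibril_like",
    "make_toy_structure",
    "simulate_psn_ensemble",
]


def _stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary row vector of a row-stochastic matrix (least-squares null space)."""
    k = P.shape[0]
    A = np.vstack([P.T - np.eye(k), np.ones((1, k))])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _angle_labels(n_residues: int) -> list[tuple[int, str]]:
    labels = []
    for r in range(1, n_residues + 1):
        labels.append((r, "phi"))
        labels.append((r, "psi"))
    return labels


def angle_index(n_residues: int, residue: int, kind: str) -> int:
    """Column index of (residue, phi|psi) in the residue-major angle layout."""
    if not 1 <= residue <= n_residues:
        raise ValueError(f"residue {residue} out of range")
    return 2 * (residue - 1) + (0 if kind == "phi" else 1)


@dataclass
class SyntheticSpec:
    """Ground-truth description of the synthetic conformational system.

    Angles are laid out residue-major: (phi_1, psi_1, phi_2, psi_2, ...),
    2 * n_residues slots.  Basins are shared across variants; a variant is a
    per-angle shift vector plus a row-stochastic basin transition matrix.
    """

    n_residues: int
    basin_means: np.ndarray            # (n_basins, 2 * n_residues)
    basin_concentrations: np.ndarray   # (n_basins, 2 * n_residues), von Mises kappa
    variant_shifts: dict               # variant id -> (2 * n_residues,) shift
    variant_transition_matrices: dict  # variant id -> (n_basins, n_basins)
    fibril_reference: tuple | None = None  # (angles, concentration)
    seed: int = 0

    def __post_init__(self):
        self.basin_means = np.atleast_2d(np.asarray(self.basin_means, float))
        self.basin_concentrations = np.broadcast_to(
            np.asarray(self.basin_concentrations, float),
            self.basin_means.shape).copy()
        if np.any(self.basin_concentrations <= 0):
            raise ValueError("von Mises concentrations must be positive")
        m = 2 * self.n_residues
        if self.basin_means.shape[1] != m:
            raise ValueError(f"basin means must have {m} angle slots")
        for v, s in self.variant_shifts.items():
            s = np.asarray(s, float)
            if np.any(s <= -np.pi) or np.any(s > np.pi):
                raise ValueError(f"shifts for {v!r} must lie in (-pi, pi]")
            self.variant_shifts[v] = s
        for v, P in self.variant_transition_matrices.items():
            P = np.asarray(P, float)
            if P.shape != (self.n_basins, self.n_basins):
                raise ValueError(f"transition matrix for {v!r} has wrong shape")
            if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError(f"transition matrix for {v!r} is not row-stochastic")
            self.variant_transition_matrices[v] = P
        self._counters: dict[str, int] = {}

    @property
    def n_basins(self) -> int:
        return self.basin_means.shape[0]

    @property
    def variants(self) -> list:
        return list(self.variant_transition_matrices)

    def angle_labels(self) -> list[tuple[int, str]]:
        return _angle_labels(self.n_residues)

    def _rng(self, tag: str, seed=None) -> np.random.Generator:
        """Deterministic sub-stream per (operation tag, call index)."""
        if seed is not None:
            return np.random.default_rng(seed)
        count = self._counters.get(tag, 0)
        self._counters[tag] = count + 1
        key = zlib.crc32(tag.encode())
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key, count)))

    def reset_streams(self) -> None:
        self._counters.clear()

    def _check_variant(self, variant) -> None:
        if variant not in self.variant_transition_matrices:
            raise KeyError(f"unknown variant {variant!r}; "
                           f"defined: {self.variants}")

    def shift_for(self, variant) -> np.ndarray:
        return np.asarray(self.variant_shifts.get(variant,
                                                  np.zeros(2 * self.n_residues)))


def two_variant_spec(n_residues: int = 40,
                     concentration: float = 8.0,
                     shift_residue: int = 22,
                     shift_kind: str = "psi",
                     shift: float = 0.35,
                     switch_a: float = 0.05,
                     seed: int = 0,
                     variant_a: str = "WT",
                     variant_b: str = "MUT") -> SyntheticSpec:
    """The default two-variant study system.

    Four shared basins placed at canonical Ramachandran regions (alpha,
    beta, PPII, left-alpha), von Mises concentration 8 (about 20 degrees of
    spread), a single injected shift (default 0.35 rad at psi_22, emulating a
    localized backbone change at a mutation site), symmetric basin switching
    for variant A and basin-dependent dwell times for variant B.
    """
    m = 2 * n_residues
    basins_phi_psi = np.array([
        (-1.05, -0.79),   # alpha helix region
        (-2.36, 2.36),    # beta sheet region
        (-1.13, 2.62),    # polyproline II region
        (1.05, 0.79),     # left-handed alpha region
    ])
    means = np.empty((4, m))
    means[:, 0::2] = basins_phi_psi[:, [0]]
    means[:, 1::2] = basins_phi_psi[:, [1]]

    shifts_b = np.zeros(m)
    shifts_b[angle_index(n_residues, shift_residue, shift_kind)] = shift

    P_a = np.full((4, 4), switch_a / 3.0)
    np.fill_diagonal(P_a, 1.0 - switch_a)
    rates_b = np.array([0.02, 0.08, 0.04, 0.06])
    P_b = rates_b[:, None] / 3.0 * np.ones((4, 4))
    np.fill_diagonal(P_b, 1.0 - rates_b)

    return SyntheticSpec(
        n_residues=n_residues,
        basin_means=means,
        basin_concentrations=np.full((4, m), concentration),
        variant_shifts={variant_a: np.zeros(m), variant_b: shifts_b},
        variant_transition_matrices={variant_a: P_a, variant_b: P_b},
        fibril_reference=(means[1].copy(), 64.0),  # tight around the beta basin
        seed=seed,
    )


def shift_only_spec(n_residues: int = 40,
                    concentration: float = 8.0,
                    shift_residue: int = 22,
                    shift_kind: str = "psi",
                    shift: float = 0.35,
                    seed: int = 0,
                    variant_a: str = "WT",
                    variant_b: str = "MUT") -> SyntheticSpec:
    """Two variants differing *only* by one small angle shift.

    A single basin (alpha region) with identical trivial kinetics for both
    variants isolates the site-specific shift as the sole class difference —
    the cleanest regime for boundary-crossing shift recovery.
    """
    m = 2 * n_residues
    means = np.empty((1, m))
    means[0, 0::2] = -1.05
    means[0, 1::2] = -0.79
    shifts_b = np.zeros(m)
    shifts_b[angle_index(n_residues, shift_residue, shift_kind)] = shift
    P = np.ones((1, 1))
    return SyntheticSpec(
        n_residues=n_residues,
        basin_means=means,
        basin_concentrations=np.full((1, m), concentration),
        variant_shifts={variant_a: np.zeros(m), variant_b: shifts_b},
        variant_transition_matrices={variant_a: P, variant_b: P.copy()},
        fibril_reference=(means[0].copy(), 64.0),
        seed=seed,
    )


def _emit(rng: np.random.Generator, mu: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Von Mises draws; infinite concentration collapses to the mean."""
    finite = np.isfinite(kappa)
    out = np.where(finite, 0.0, mu)
    if np.any(finite):
        draw = rng.vonmises(mu, np.where(finite, kappa, 1.0))
        out = np.where(finite, draw, out)
    return wrap_angle(out)


def sample_conformations(spec: SyntheticSpec, variant, n: int,
                         seed=None) -> ConformationSet:
    """Draw n conformations for a variant from its basin mixture.

    Basins are drawn from the stationary distribution of the variant's
    transition matrix; each angle is von Mises around basin mean + variant
    shift.
    """
    spec._check_variant(variant)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = spec._rng(f"conf:{variant}", seed)
    P = spec.variant_transition_matrices[variant]
    pi = _stationary_distribution(P)
    basins = rng.choice(spec.n_basins, size=n, p=pi)
    mu = wrap_angle(spec.basin_means[basins] + spec.shift_for(variant))
    angles = _emit(rng, mu, spec.basin_concentrations[basins])
    return ConformationSet(angles, spec.angle_labels(),
                           np.array([variant] * n),
                           np.array([f"{variant}:{i}" for i in range(n)]))


def simulate_trajectory(spec: SyntheticSpec, variant, n_steps: int,
                        dt: float = 2.0, start_basin: int | None = None,
                        seed=None) -> TrajectorySegment:
    """Hidden-Markov trajectory over basins with von Mises emissions.

    The hidden basin path is returned alongside as ground truth.  Times are
    uniformly spaced by `dt` picoseconds.
    """
    spec._check_variant(variant)
    if n_steps < 2:
        raise ValueError("a trajectory needs at least 2 steps")
    rng = spec._rng(f"traj:{variant}", seed)
    P = spec.variant_transition_matrices[variant]
    states = np.empty(n_steps, dtype=int)
    if start_basin is None:
        states[0] = rng.choice(spec.n_basins, p=_stationary_distribution(P))
    else:
        states[0] = start_basin
    for t in range(1, n_steps):
        states[t] = rng.choice(spec.n_basins, p=P[states[t - 1]])
    mu = wrap_angle(spec.basin_means[states] + spec.shift_for(variant))
    angles = _emit(rng, mu, spec.basin_concentrations[states])
    conf = ConformationSet(angles, spec.angle_labels(),
                           np.array([variant] * n_steps),
                           np.array([f"{variant}:t{t}" for t in range(n_steps)]))
    return TrajectorySegment(conf, dt * np.arange(n_steps), states)


def sample_fibril_like(spec: SyntheticSpec, n: int, seed=None,
                       label: str = "fibril") -> ConformationSet:
    """Conformations tightly concentrated on the fibril reference angles."""
    if spec.fibril_reference is None:
        raise ValueError("spec has no fibril_reference")
    ref, kappa = spec.fibril_reference
    ref = np.asarray(ref, float)
    m = ref.shape[0]
    if n == 0:
        return ConformationSet(np.empty((0, m)), spec.angle_labels(),
                               np.empty(0, dtype=object), np.empty(0, dtype=object))
    rng = spec._rng("fibril", seed)
    mu = np.broadcast_to(ref, (n, m))
    kap = np.broadcast_to(np.asarray(kappa, float), (n, m))
    angles = _emit(rng, mu, kap)
    return ConformationSet(angles, spec.angle_labels(),
                           np.array([label] * n),
                           np.array([f"{label}:{i}" for i in range(n)]))


@dataclass
class ToyStructure:
    """Sphere-per-residue coordinate carrier for contact-rule tests.

    One atom per residue by default; arbitrary atoms supported via the
    (residue_index, element_key, xyz) triples.
    """

    residue_index: np.ndarray  # 1-based, contiguous
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Angstrom

    def __post_init__(self):
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        uniq = np.unique(self.residue_index)
        if not np.array_equal(uniq, np.arange(1, uniq.max() + 1)):
            raise ValueError("residue indices must be contiguous from 1")

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max())

    def atoms_iter(self):
        for ridx, elem, xyz in zip(self.residue_index, self.elements, self.coords):
            yield int(ridx), elem, xyz

    def to_pdb(self, path) -> None:
        """Minimal single-model PDB with one ATOM record per atom."""
        lines = []
        for serial, (ridx, elem, xyz) in enumerate(self.atoms_iter(), start=1):
            name = elem.upper().rjust(2)
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} GLY A{ridx:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {elem.upper():>2s}")
        lines.append("END")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _arc_layout(n: int, spacing: float) -> np.ndarray:
    """Points on a semicircular arc with consecutive chord length `spacing`.

    Chord length grows monotonically with index separation on an arc of at
    most pi radians, so the layout realizes an empty contact map for any n.
    """
    if n == 1:
        return np.zeros((1, 3))
    step = np.pi / max(n - 1, 2)
    radius = spacing / (2.0 * np.sin(step / 2.0))
    th = step * np.arange(n)
    return np.column_stack([radius * np.cos(th), radius * np.sin(th),
                            np.zeros(n)])


def make_toy_structure(target_contacts, n_residues: int,
                       radii: dict[str, float] | None = None,
                       element: str = "C", factor: float = 1.2,
                       seed: int = 0, max_tries: int = 8) -> ToyStructure:
    """Place one sphere per residue so that the contact-rule PSN reproduces
    exactly the requested non-backbone contact set plus the backbone path.

    Consecutive residues sit at 0.9x the contact threshold; target contacts
    are pulled below the threshold and all other pairs pushed above it by a
    penalized stress optimization, verified exactly by a PSN round-trip.
    Raises if the map cannot be realized at the requested tolerance.
    """
    from .psn import build_psn  # local import to avoid a cycle

    radii = dict(VDW_RADII if radii is None else radii)
    r = radii[element.upper()]
    thr = factor * 2.0 * r
    target = {tuple(sorted(p)) for p in target_contacts}
    for i, j in target:
        if not (1 <= i < j <= n_residues):
            raise ValueError(f"contact {(i, j)} out of range")
        if j - i == 1:
            raise ValueError(f"contact {(i, j)} is a backbone pair; "
                             "backbone edges are implicit")
    n = n_residues
    pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]

    def stress(flat):
        x = flat.reshape(n, 3)
        val = 0.0
        grad = np.zeros_like(x)
        for i, j in pairs:
            d_vec = x[i - 1] - x[j - 1]
            d = np.linalg.norm(d_vec) + 1e-12
            if j - i == 1:
                tgt, springy = 0.9 * thr, True
            elif (i, j) in target:
                tgt, springy = 0.85 * thr, True
            else:
                tgt, springy = 1.25 * thr, False
            if springy:
                c = d - tgt
            else:
                c = min(0.0, d - tgt)  # one-sided: only penalize being too close
            if c != 0.0:
                val += c * c
                g = 2.0 * c * d_vec / d
                grad[i - 1] += g
                grad[j - 1] -= g
        return val, grad.ravel()

    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        x0 = _arc_layout(n, 0.9 * thr)
        if attempt > 0:
            x0 = x0 + rng.normal(scale=0.3 * thr, size=x0.shape)
        res = minimize(stress, x0.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12})
        coords = res.x.reshape(n, 3)
        structure = ToyStructure(np.arange(1, n + 1), [element] * n, coords)
        psn = build_psn(structure, radii, factor)
        realized = {(i, j) for i, j, bb in psn.edges() if not bb}
        if realized == target:
            return structure
    raise ValueError(f"contact map {sorted(target)} not realizable at the "
                     f"requested tolerance after {max_tries} attempts")


def simulate_psn_ensemble(model: ErgmModel, props: ResidueProperties, n: int,
                          burn: int | None = None, thin: int | None = None,
                          seed: int = 0):
    """PSN ensemble drawn from an ERGM (delegates to the Metropolis sampler)."""
    return simulate_ergm(model, props, n, burn=burn, thin=thin, seed=seed)
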