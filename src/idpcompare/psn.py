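"""Residue-level protein structure networks (PSNs).

A PSN places one node per residue and one edge per inter-residue atomic
contact: residues i and j are in contact when some atom of i lies within
1.2 times the sum of the two atoms' van der Waals radii of some atom of j
(strict inequality).  Backbone neighbours (i, i+1) are always connected and
their edges flagged; they form the fixed support of the ERGM analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import fisher_exact, norm, ttest_ind

from .properties import VDW_RADII

__all__ = [
    "PSN",
    "CoreProfile",
    "build_psn",
    "core_numbers",
    "core_profile_contrast",
    "edge_frequency_contrast",
]


@dataclass
class PSN:
    """Simple undirected graph on residues 1..n with mandatory backbone path.

    Internally adjacency is a symmetric boolean matrix (0-based); all
    reported residue pairs are 1-based.
    """

    adjacency: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(a != a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("no self-loops allowed")
        idx = np.arange(a.shape[0] - 1)
        if not np.all(a[idx, idx + 1]):
            raise ValueError("all backbone-path edges (i, i+1) must be present")
        self.adjacency = a

    @classmethod
    def from_edges(cls, n_nodes: int, edges, provenance: str = "") -> "PSN":
        """Build from 1-based residue pairs; backbone edges are added implicitly."""
        a = np.zeros((n_nodes, n_nodes), dtype=bool)
        idx = np.arange(n_nodes - 1)
        a[idx, idx + 1] = a[idx + 1, idx] = True
        for i, j in edges:
            if i == j:
                raise ValueError("self-loop")
            a[i - 1, j - 1] = a[j - 1, i - 1] = True
        return cls(a, provenance)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def is_backbone(self, i: int, j: int) -> bool:
        """Backbone flag for a 1-based residue pair."""
        return abs(i - j) == 1

    def edges(self, include_backbone: bool = True) -> list[tuple[int, int, bool]]:
        """Sorted (i, j, backbone_flag) with i < j, 1-based."""
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        out = []
        for i, j in zip(iu + 1, ju + 1):
            bb = self.is_backbone(i, j)
            if bb and not include_backbone:
                continue
            out.append((int(i), int(j), bb))
        return out

    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def free_dyads(self) -> np.ndarray:
        """All non-backbone dyads as an (m, 2) array of 1-based pairs, i < j."""
        n = self.n_nodes
        iu, ju = np.triu_indices(n, 2)  # offset 2 excludes the backbone diagonal
        return np.column_stack([iu + 1, ju + 1])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(1, self.n_nodes + 1))
        for i, j, bb in self.edges():
            g.add_edge(i, j, backbone=bb)
        return g

    def copy(self) -> "PSN":
        return PSN(self.adjacency.copy(), self.provenance)

    # edge-list text serialization: "i j backbone_flag"
    def to_edgelist(self) -> str:
        lines = [f"# nodes {self.n_nodes} provenance {self.provenance}"]
        lines += [f"{i} {j} {int(bb)}" for i, j, bb in self.edges()]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edgelist(cls, text: str) -> "PSN":
        lines = [ln for ln in text.strip().splitlines()]
        header = lines[0].split()
        n = int(header[2])
        prov = header[4] if len(header) > 4 else ""
        edges = []
        for ln in lines[1:]:
            i, j, _ = ln.split()
            edges.append((int(i), int(j)))
        return cls.from_edges(n, edges, prov)


def _iter_atoms(structure):
    """Yield (residue_index_1based, element_key, xyz) triples."""
    if hasattr(structure, "atoms_iter"):
        yield from structure.atoms_iter()
        return
    # Bio.PDB Chain or Model
    from Bio.PDB.Chain import Chain
    from Bio.PDB.Model import Model

    if isinstance(structure, Model):
        chains = list(structure)
        if len(chains) != 1:
            raise ValueError("pass a single chain for PSN construction")
        structure = chains[0]
    if not isinstance(structure, Chain):
        raise TypeError(f"unsupported structure type {type(structure)!r}")
    residues = [r for r in structure if r.id[0] == " "]
    for ridx, res in enumerate(residues, start=1):
        for atom in res:
            yield ridx, (atom.element or atom.get_name()[0]).upper(), \
                atom.get_coord().astype(float)


def build_psn(structure, radii: dict[str, float] | None = None,
              factor: float = 1.2, heavy_atoms_only: bool = False,
              provenance: str = "") -> PSN:
    """Contact-rule PSN: edge (i, j) iff some atom pair is closer than
    `factor` times the sum of its van der Waals radii (strict inequality).

    Backbone edges (i, i+1) are added unconditionally.  Contact search uses a
    KD-tree with the maximal possible contact distance as cutoff, then exact
    per-pair radius checks; this is identical to an all-pairs scan.
    """
    radii = dict(VDW_RADII if radii is None else radii)
    res_idx, rads, coords = [], [], []
    for ridx, key, xyz in _iter_atoms(structure):
        key = key.upper()
        if heavy_atoms_only and key == "H":
            continue
        if key not in radii:
            raise KeyError(f"no van der Waals radius for atom key {key!r}")
        res_idx.append(ridx)
        rads.append(radii[key])
        coords.append(xyz)
    if not res_idx:
        raise ValueError("structure has no atoms")
    res_idx = np.asarray(res_idx)
    rads = np.asarray(rads)
    coords = np.asarray(coords, dtype=float)
    n = int(res_idx.max())
    if n < 2:
        raise ValueError("PSN needs at least 2 residues")
    a = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    a[idx, idx + 1] = a[idx + 1, idx] = True

    tree = cKDTree(coords)
    cutoff = factor * 2.0 * rads.max()
    for p, q in tree.query_pairs(cutoff):
        ri, rj = res_idx[p], res_idx[q]
        if ri == rj:
            continue
        d = np.linalg.norm(coords[p] - coords[q])
        if d < factor * (rads[p] + rads[q]):
            a[ri - 1, rj - 1] = a[rj - 1, ri - 1] = True
    return PSN(a, provenance)


def core_numbers(psn: PSN) -> np.ndarray:
    """Degree-core number per residue (1-based order), via networkx."""
    import networkx as nx

    cn = nx.core_number(psn.to_networkx())
    return np.array([cn[i] for i in range(1, psn.n_nodes + 1)])


@dataclass
class CoreProfile:
    """Per-residue mean core number with 95% CI over an ensemble."""

    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_graphs: int


def _core_matrix(ensemble: list[PSN]) -> np.ndarray:
    return np.array([core_numbers(g) for g in ensemble])


def core_profile(ensemble: list[PSN], level: float = 0.95) -> CoreProfile:
    m = _core_matrix(ensemble)
    mean = m.mean(axis=0)
    z = norm.ppf(0.5 + level / 2.0)
    se = m.std(axis=0, ddof=1) / np.sqrt(m.shape[0]) if m.shape[0] > 1 \
        else np.zeros(m.shape[1])
    return CoreProfile(mean, mean - z * se, mean + z * se, m.shape[0])


def core_profile_contrast(ensemble_a: list[PSN], ensemble_b: list[PSN],
                          alpha: float = 0.05) -> pd.DataFrame:
    """Welch-test contrast of per-residue mean core numbers between ensembles.

    Returns one row per residue: means, CIs, Welch p-value and a flag in
    {-1, 0, +1} (+1 = significantly higher in ensemble B).
    """
    if not ensemble_a or not ensemble_b:
        raise ValueError("both ensembles must be non-empty")
    if ensemble_a[0].n_nodes != ensemble_b[0].n_nodes:
        raise ValueError("ensembles have different node counts")
    ma, mb = _core_matrix(ensemble_a), _core_matrix(ensemble_b)
    pa, pb = core_profile(ensemble_a), core_profile(ensemble_b)
    n_res = ma.shape[1]
    pvals = np.ones(n_res)
    for r in range(n_res):
        if np.ptp(ma[:, r]) == 0 and np.ptp(mb[:, r]) == 0:
            pvals[r] = 1.0 if ma[0, r] == mb[0, r] else 0.0
            continue
        pvals[r] = ttest_ind(ma[:, r], mb[:, r], equal_var=False).pvalue
    diff = pb.mean - pa.mean
    flag = np.where(pvals < alpha, np.sign(diff).astype(int), 0)
    return pd.DataFrame({
        "residue": np.arange(1, n_res + 1),
        "mean_a": pa.mean, "lo_a": pa.ci_low, "hi_a": pa.ci_high,
        "mean_b": pb.mean, "lo_b": pb.ci_low, "hi_b": pb.ci_high,
        "difference": diff, "p_value": pvals, "flag": flag,
    })


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided two-proportion z-test with continuity correction.

    Falls back to Fisher's exact test when any expected cell count under the
    pooled proportion is below 5.
    """
    p_pool = (x1 + x2) / (n1 + n2)
    expected = np.array([n1 * p_pool, n1 * (1 - p_pool),
                         n2 * p_pool, n2 * (1 - p_pool)])
    if np.any(expected < 5):
        table = [[x1, n1 - x1], [x2, n2 - x2]]
        return float(fisher_exact(table)[1])
    p1, p2 = x1 / n1, x2 / n2
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    cc = 0.5 * (1 / n1 + 1 / n2)
    z = (abs(p1 - p2) - cc) / se
    z = max(z, 0.0)
    return float(2 * norm.sf(z))


def edge_frequency_contrast(ensemble_a: list[PSN], ensemble_b: list[PSN],
                            alpha: float = 0.05) -> pd.DataFrame:
    """Per-dyad edge-frequency contrast between two PSN ensembles.

    Backbone dyads are excluded (always present by construction).  Each
    non-backbone dyad gets frequencies in both ensembles, their difference
    (B - A), a two-proportion test p-value, a flag in {-1, 0, +1} and a
    rendering magnitude = |difference|.
    """
    if not ensemble_a or not ensemble_b:
        raise ValueError("both ensembles must be non-empty")
    n = ensemble_a[0].n_nodes
    na, nb = len(ensemble_a), len(ensemble_b)
    counts_a = sum(g.adjacency.astype(int) for g in ensemble_a)
    counts_b = sum(g.adjacency.astype(int) for g in ensemble_b)
    rows = []
    for i in range(1, n + 1):
        for j in range(i + 2, n + 1):
            xa = int(counts_a[i - 1, j - 1])
            xb = int(counts_b[i - 1, j - 1])
            fa, fb = xa / na, xb / nb
            if xa == xb == 0 or (xa == na and xb == nb):
                p = 1.0
            else:
                p = two_proportion_test(xa, na, xb, nb)
            diff = fb - fa
            flag = int(np.sign(diff)) if p < alpha else 0
            rows.append((i, j, fa, fb, diff, abs(diff), p, flag))
    return pd.DataFrame(rows, columns=[
        "i", "j", "freq_a", "freq_b", "difference", "magnitude",
        "p_value", "flag"])
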