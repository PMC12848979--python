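"""Fully synthetic toy systems for exercising the pipeline end to end.

Everything here is a pure function of its seed.  Geometries are
chemically plausible but fictitious: they reproduce the *structural*
features the contact analysis cares about (donor/acceptor geometry,
surface burial, AIP spacing) without mimicking real residues beyond graph
topology, so no external structure files are ever needed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .aip_core import AIP, AipClass, AtomSite, Hybridization, MoleculeGraph
from .fragment_matching import FragmentRecord, fragment_from_molecule

__all__ = [
    "ToySystemSpec",
    "make_toy_complex",
    "make_toy_fragment_library",
    "make_backbone_chain",
    "enumerate_best_matching",
]


@dataclass
class ToySystemSpec:
    """Recipe for a synthetic protein-ligand test system.

    ``template`` selects the engineered geometry: ``hbond`` (one ideal
    donor/acceptor pair), ``nonpolar_grid`` (CH-like AIP rows with a
    unique optimal pairing), ``clash`` (two strong donors forced together)
    or ``buried_exposed`` (pocket AIPs retained, protruding AIP solvated).
    """

    template: str = "hbond"
    n_ligand_aips: int = 3
    n_protein_aips: int = 3
    eps_range: tuple[float, float] = (0.3, 1.5)
    n_decoys: int = 0
    seed: int = 0


def _atom(aid, element, coords, hyb=Hybridization.SP3, sybyl=""):
    return AtomSite(atom_id=aid, element=element, coords=np.asarray(coords, float),
                    hybridization=hyb, sybyl_type=sybyl)


def _chain_bonds(ids):
    return [(a, b, 1.0) for a, b in zip(ids, ids[1:])]


def _ch_aip(pos, eps, parent):
    return AIP(position=pos, epsilon=eps, fraction=1.0,
               aip_class=AipClass.CH_DONOR, parent_atom_id=parent)


# ---------------------------------------------------------------------------
# Exhaustive matching oracle (kept independent of the contact engine)
# ---------------------------------------------------------------------------

def enumerate_best_matching(edges: list[tuple[int, int, float]],
                            n_ligand: int) -> tuple[int, float, frozenset]:
    """Brute-force optimum of the (cardinality, total distance) objective.

    ``edges`` are (ligand index, protein index, distance).  Returns
    (max cardinality, min total distance among maximum matchings, one
    optimal edge set).  Pure recursion over ligand indices: each either
    stays unmatched or takes one of its unused partners.
    """
    by_lig: dict[int, list[tuple[int, float]]] = {}
    for li, pi, d in edges:
        by_lig.setdefault(li, []).append((pi, d))

    best = (0, 0.0, frozenset())

    def rec(li, used, card, dist, chosen):
        nonlocal best
        if li == n_ligand:
            cand = (card, dist, frozenset(chosen))
            if (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand
            return
        rec(li + 1, used, card, dist, chosen)
        for pi, d in by_lig.get(li, []):
            if pi not in used:
                rec(li + 1, used | {pi}, card + 1, dist + d, chosen + [(li, pi)])

    rec(0, frozenset(), 0, 0.0, [])
    return best


# ---------------------------------------------------------------------------
# Toy complexes
# ---------------------------------------------------------------------------

def make_toy_complex(spec: ToySystemSpec):
    """Build (protein, ligand, ground_truth) for the requested template.

    ``ground_truth`` lists (ligand AIP index, protein AIP index,
    contact type) for the contacts the pipeline must recover; for the
    nonpolar grid it is the provably optimal assignment (verified with
    :func:`enumerate_best_matching` at generation time).
    """
    builders = {"hbond": _toy_hbond, "nonpolar_grid": _toy_grid,
                "clash": _toy_clash, "buried_exposed": _toy_buried}
    if spec.template not in builders:
        raise ValueError(f"unknown template {spec.template!r}")
    protein, ligand, truth = builders[spec.template](spec)
    for mol in (protein, ligand):
        _check_no_overlap(mol)
    return protein, ligand, truth


def _check_no_overlap(mol: MoleculeGraph) -> None:
    coords = mol.coords_array()
    if len(coords) < 2:
        return
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < 0.5:
        raise ValueError("infeasible toy geometry: overlapping atoms")


def _toy_hbond(spec: ToySystemSpec):
    """One ideal O-H...O=C hydrogen bond across the interface."""
    rng = np.random.default_rng(spec.seed)
    # protein: C-O-H donor arm
    p_atoms = [
        _atom("pC1", "C", (-1.4, 0.0, 0.0), Hybridization.SP3, "C.3"),
        _atom("pO1", "O", (0.0, 0.0, 0.0), Hybridization.SP3, "O.3.alcohol"),
        _atom("pH1", "H", (0.97, 0.0, 0.0), Hybridization.NONE, "H.O"),
    ]
    # pocket collar shields the interface AIPs from solvent
    for k, (y, z) in enumerate([(3.0, 0.0), (-3.0, 0.0), (0.0, 3.0), (0.0, -3.0)]):
        p_atoms.append(_atom(f"pW{k}", "C", (2.0, y, z), Hybridization.SP3, "C.3"))
    protein = MoleculeGraph(
        atoms=p_atoms,
        bonds=_chain_bonds(["pC1", "pO1", "pH1"]) +
        [("pC1", f"pW{k}", 1.0) for k in range(4)])
    protein.aips.append(AIP(position=np.array([1.9, 0.0, 0.0]), epsilon=3.7,
                            fraction=1.0, aip_class=AipClass.POLAR_H,
                            parent_atom_id="pH1"))
    # ligand: carbonyl acceptor
    l_atoms = [
        _atom("lO1", "O", (2.8, 0.0, 0.0), Hybridization.SP2, "O.2.other"),
        _atom("lC1", "C", (4.02, 0.0, 0.0), Hybridization.SP2, "C.2"),
        _atom("lC2", "C", (4.75, 1.25, 0.0), Hybridization.SP3, "C.3"),
    ]
    ligand = MoleculeGraph(atoms=l_atoms,
                           bonds=[("lO1", "lC1", 2.0), ("lC1", "lC2", 1.0)])
    ligand.aips.append(AIP(position=np.array([1.6, 0.0, 0.0]), epsilon=-5.5,
                           fraction=1.0, aip_class=AipClass.LONE_PAIR,
                           parent_atom_id="lO1"))
    truth = [(0, 0, "hbond")]
    _add_decoys(spec, rng, protein, ligand)
    return protein, ligand, truth


def _add_decoys(spec, rng, protein, ligand):
    """Nonpolar decoy AIPs placed > 2.5 A from every other AIP (outside
    every pairing threshold)."""
    for k in range(spec.n_decoys):
        side, mol = (("p", protein) if k % 2 == 0 else ("l", ligand))
        base = mol.atoms[0].coords
        aid = f"{side}D{k}"
        offset = np.array([0.0, 4.0 + 3.0 * k, 6.0])
        mol.atoms.append(_atom(aid, "C", base + offset, Hybridization.SP3, "C.3"))
        mol.bonds.append((mol.atoms[0].atom_id, aid, 1.0))
        eps = float(rng.uniform(*spec.eps_range))
        mol.aips.append(_ch_aip(base + offset + np.array([0.0, 0.0, 1.9]), eps, aid))


def _toy_grid(spec: ToySystemSpec):
    """Rows of CH-like AIPs with a unique optimal bipartite assignment."""
    for attempt in range(64):
        rng = np.random.default_rng((spec.seed, attempt))
        protein, ligand = _grid_geometry(spec, rng)
        edges = [(i, j, float(np.linalg.norm(lp.position - pp.position)))
                 for i, lp in enumerate(ligand.aips)
                 for j, pp in enumerate(protein.aips)
                 if np.linalg.norm(lp.position - pp.position) < 1.7]
        card, dist, chosen = enumerate_best_matching(edges, len(ligand.aips))
        if card == 0:
            continue
        unique = _optimum_is_unique(edges, len(ligand.aips), card, dist, chosen)
        if unique:
            truth = sorted((li, pi, "nonpolar") for li, pi in chosen)
            return protein, ligand, truth
    raise ValueError("could not realise a unique-optimum grid for this spec")


def _optimum_is_unique(edges, n_lig, card, dist, chosen):
    count = 0

    def rec(li, used, c, d, sel):
        nonlocal count
        if count > 1:
            return
        if li == n_lig:
            if c == card and abs(d - dist) < 1e-9:
                count += 1
            return
        rec(li + 1, used, c, d, sel)
        for pi, dd in [(p, w) for l, p, w in edges if l == li]:
            if pi not in used:
                rec(li + 1, used | {pi}, c + 1, d + dd, sel)

    rec(0, frozenset(), 0, 0.0, [])
    return count == 1


def _grid_geometry(spec, rng):
    nl, np_ = spec.n_ligand_aips, spec.n_protein_aips
    lo, hi = spec.eps_range
    l_atoms, l_aips, l_ids = [], [], []
    for i in range(nl):
        cid, hid = f"lC{i}", f"lH{i}"
        x = 2.6 * i
        l_atoms += [_atom(cid, "C", (x, 0.0, 0.0), Hybridization.SP3, "C.3"),
                    _atom(hid, "H", (x, 1.09, 0.0), Hybridization.NONE, "H.soft")]
        l_ids += [cid, hid]
        l_aips.append(_ch_aip(np.array([x, 2.1, 0.0]), float(rng.uniform(lo, hi)), hid))
    l_bonds = [(f"lC{i}", f"lC{i+1}", 1.0) for i in range(nl - 1)] + \
              [(f"lC{i}", f"lH{i}", 1.0) for i in range(nl)]
    ligand = MoleculeGraph(atoms=l_atoms, bonds=l_bonds, aips=l_aips)

    p_atoms, p_aips = [], []
    for j in range(np_):
        cid, hid = f"pC{j}", f"pH{j}"
        x = 2.6 * j + float(rng.uniform(-0.9, 0.9))
        y = 4.4
        p_atoms += [_atom(cid, "C", (x, y + 1.09, 0.0), Hybridization.SP3, "C.3"),
                    _atom(hid, "H", (x, y, 0.0), Hybridization.NONE, "H.soft")]
        p_aips.append(_ch_aip(np.array([x, y - 1.0 - float(rng.uniform(0, 0.6)), 0.0]),
                              -float(rng.uniform(lo, hi)), hid))
    p_bonds = [(f"pC{j}", f"pC{j+1}", 1.0) for j in range(np_ - 1)] + \
              [(f"pC{j}", f"pH{j}", 1.0) for j in range(np_)]
    # side walls bury the interface so the engineered AIPs pass the
    # exposure filter, as they would in a real binding pocket
    xs = [a.coords[0] for a in p_atoms + l_atoms]
    k = 0
    for x in np.arange(min(xs) - 1.3, max(xs) + 1.4, 1.8):
        for s in (+1.0, -1.0):
            wid = f"pWall{k}"
            p_atoms.append(_atom(wid, "C", (float(x), 2.7, s * 2.3),
                                 Hybridization.SP3, "C.3"))
            p_bonds.append(("pC0", wid, 1.0))
            k += 1
    protein = MoleculeGraph(atoms=p_atoms, bonds=p_bonds, aips=p_aips)
    return protein, ligand


def _toy_clash(spec: ToySystemSpec):
    """Two strong H-bond donors forced into contact (a hydrogen-placement
    pathology): the pairing succeeds but the clamped contact pays double
    desolvation, so its ddG is strongly repulsive."""
    p_atoms = [
        _atom("pC1", "C", (-1.4, 0.0, 0.0), Hybridization.SP3, "C.3"),
        _atom("pO1", "O", (0.0, 0.0, 0.0), Hybridization.SP3, "O.3.alcohol"),
        _atom("pH1", "H", (0.97, 0.0, 0.0), Hybridization.NONE, "H.O"),
    ]
    for k, (y, z) in enumerate([(3.0, 0.0), (-3.0, 0.0), (0.0, 3.0), (0.0, -3.0)]):
        p_atoms.append(_atom(f"pW{k}", "C", (2.1, y, z), Hybridization.SP3, "C.3"))
    protein = MoleculeGraph(
        atoms=p_atoms,
        bonds=_chain_bonds(["pC1", "pO1", "pH1"]) +
        [("pC1", f"pW{k}", 1.0) for k in range(4)])
    protein.aips.append(AIP(position=np.array([1.9, 0.0, 0.0]), epsilon=4.0,
                            fraction=1.0, aip_class=AipClass.POLAR_H,
                            parent_atom_id="pH1"))
    l_atoms = [
        _atom("lH1", "H", (3.25, 0.0, 0.0), Hybridization.NONE, "H.O"),
        _atom("lO1", "O", (4.22, 0.0, 0.0), Hybridization.SP3, "O.3.alcohol"),
        _atom("lC1", "C", (5.62, 0.0, 0.0), Hybridization.SP3, "C.3"),
    ]
    ligand = MoleculeGraph(atoms=l_atoms, bonds=_chain_bonds(["lH1", "lO1", "lC1"]))
    ligand.aips.append(AIP(position=np.array([2.3, 0.0, 0.0]), epsilon=3.5,
                           fraction=1.0, aip_class=AipClass.POLAR_H,
                           parent_atom_id="lH1"))
    return protein, ligand, [(0, 0, "nonpolar")]


def _toy_buried(spec: ToySystemSpec):
    """A pocket AIP shielded by a cage (retained by the SASA filter) next
    to a protruding AIP on an isolated arm (eliminated)."""
    cage_centre = np.zeros(3)
    p_atoms = [_atom("pC0", "C", cage_centre, Hybridization.SP3, "C.3")]
    bonds = []
    directions = [v for v in itertools.product((-1.0, 1.0), repeat=3)]
    for k, v in enumerate(directions):
        aid = f"pC{k+1}"
        p_atoms.append(_atom(aid, "C", 2.6 * np.asarray(v) / math.sqrt(3),
                             Hybridization.SP3, "C.3"))
        bonds.append(("pC0", aid, 1.0))
    arm = np.array([9.0, 0.0, 0.0])
    p_atoms.append(_atom("pArm", "C", arm, Hybridization.SP3, "C.3"))
    bonds.append(("pC1", "pArm", 1.0))
    protein = MoleculeGraph(atoms=p_atoms, bonds=bonds)
    protein.aips.append(_ch_aip(cage_centre + np.array([1.9, 0.0, 0.0]), 0.8, "pC0"))
    protein.aips.append(_ch_aip(arm + np.array([2.05, 0.0, 0.0]), 0.6, "pArm"))

    l_atoms = [_atom("lC0", "C", (0.0, 6.5, 0.0), Hybridization.SP3, "C.3"),
               _atom("lC1", "C", (1.54, 6.5, 0.0), Hybridization.SP3, "C.3")]
    ligand = MoleculeGraph(atoms=l_atoms, bonds=[("lC0", "lC1", 1.0)])
    ligand.aips.append(_ch_aip(np.array([0.0, 4.6, 0.0]), -0.5, "lC0"))
    # ground truth: only the exposed protein AIP (index 1) is eliminated
    return protein, ligand, [("eliminated", 1, "sasa")]


# ---------------------------------------------------------------------------
# Geometry helpers for the fragment library
# ---------------------------------------------------------------------------

def _orthonormal(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = v / np.linalg.norm(v)
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u1 = np.cross(v, ref)
    u1 /= np.linalg.norm(u1)
    return u1, np.cross(v, u1)


def _methyl_hydrogens(carbon: np.ndarray, toward: np.ndarray,
                      bond: float = 1.09) -> list[np.ndarray]:
    """Three tetrahedral H positions on a carbon whose fourth substituent
    lies in direction ``toward``."""
    axis = (carbon - toward)
    axis /= np.linalg.norm(axis)
    u1, u2 = _orthonormal(axis)
    out = []
    for k in range(3):
        ang = 2.0 * math.pi * k / 3.0
        direction = math.cos(math.radians(70.53)) * axis + \
            math.sin(math.radians(70.53)) * (math.cos(ang) * u1 + math.sin(ang) * u2)
        out.append(carbon + bond * direction)
    return out


def _lone_pairs(heavy: np.ndarray, away_from: np.ndarray, plane_normal: np.ndarray,
                dist: float = 1.4, half_angle: float = 50.0) -> list[np.ndarray]:
    axis = heavy - away_from
    axis /= np.linalg.norm(axis)
    perp = np.cross(plane_normal, axis)
    perp /= np.linalg.norm(perp)
    out = []
    for s in (+1, -1):
        d = math.cos(math.radians(half_angle)) * axis + \
            s * math.sin(math.radians(half_angle)) * perp
        out.append(heavy + dist * d)
    return out


def _add_ch_aips(mol, h_ids, eps):
    index = mol._index()
    for hid in h_ids:
        h = index[hid]
        parent = index[mol.neighbors(hid)[0]]
        d = h.coords - parent.coords
        d /= np.linalg.norm(d)
        mol.aips.append(_ch_aip(h.coords + 1.1 * d, eps, hid))


def _nma_graph() -> MoleculeGraph:
    """N-methylacetamide with AIPs on the amide unit and the CH surface."""
    c1 = np.array([-1.52, 0.0, 0.0])
    c2 = np.zeros(3)
    o = np.array([0.58, 1.07, 0.0])
    n = np.array([0.66, -1.16, 0.0])
    hn = np.array([1.67, -1.17, 0.0])
    c3 = np.array([0.06, -2.47, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    atoms = [
        _atom("C1", "C", c1, Hybridization.SP3, "C.3"),
        _atom("C2", "C", c2, Hybridization.SP2, "C.2"),
        _atom("O1", "O", o, Hybridization.SP2, "O.2.am"),
        _atom("N1", "N", n, Hybridization.SP2, "N.pl3.am"),
        _atom("HN1", "H", hn, Hybridization.NONE, "H.N"),
        _atom("C3", "C", c3, Hybridization.SP3, "C.3"),
    ]
    bonds = [("C1", "C2", 1.0), ("C2", "O1", 2.0), ("C2", "N1", 1.0),
             ("N1", "HN1", 1.0), ("N1", "C3", 1.0)]
    for k, pos in enumerate(_methyl_hydrogens(c1, c2)):
        atoms.append(_atom(f"H1{k}", "H", pos, Hybridization.NONE, "H.soft"))
        bonds.append(("C1", f"H1{k}", 1.0))
    for k, pos in enumerate(_methyl_hydrogens(c3, n)):
        atoms.append(_atom(f"H3{k}", "H", pos, Hybridization.NONE, "H.soft"))
        bonds.append(("C3", f"H3{k}", 1.0))
    mol = MoleculeGraph(atoms=atoms, bonds=bonds)
    for pos in _lone_pairs(o, c2, z):
        mol.aips.append(AIP(position=pos, epsilon=-7.2, fraction=1.0,
                            aip_class=AipClass.LONE_PAIR, parent_atom_id="O1"))
    d = hn - n
    d /= np.linalg.norm(d)
    mol.aips.append(AIP(position=hn + 1.1 * d, epsilon=2.6, fraction=1.0,
                        aip_class=AipClass.POLAR_H, parent_atom_id="HN1"))
    mol.aips.append(AIP(position=n + np.array([0.0, 0.0, 1.6]), epsilon=-0.4,
                        fraction=0.5, aip_class=AipClass.PI_SITE,
                        parent_atom_id="N1"))
    _add_ch_aips(mol, [f"H1{k}" for k in range(3)] + [f"H3{k}" for k in range(3)], 0.3)
    return mol


def _nmf_graph() -> MoleculeGraph:
    """N-methylformamide: the amide unit truncated at the carbonyl carbon.

    The formyl hydrogen carries no AIP: it is a pure truncation marker
    that stands in for the carbon chain continuing on the carbonyl side,
    which lets the fragment tile consecutive amide units of a backbone.
    """
    c2 = np.zeros(3)
    hc = np.array([-1.10, 0.05, 0.0])
    o = np.array([0.58, 1.07, 0.0])
    n = np.array([0.66, -1.16, 0.0])
    hn = np.array([1.67, -1.17, 0.0])
    c3 = np.array([0.06, -2.47, 0.0])
    atoms = [
        _atom("C2", "C", c2, Hybridization.SP2, "C.2"),
        _atom("HC2", "H", hc, Hybridization.NONE, "H.soft"),
        _atom("O1", "O", o, Hybridization.SP2, "O.2.am"),
        _atom("N1", "N", n, Hybridization.SP2, "N.pl3.am"),
        _atom("HN1", "H", hn, Hybridization.NONE, "H.N"),
        _atom("C3", "C", c3, Hybridization.SP3, "C.3"),
    ]
    bonds = [("C2", "HC2", 1.0), ("C2", "O1", 2.0), ("C2", "N1", 1.0),
             ("N1", "HN1", 1.0), ("N1", "C3", 1.0)]
    for k, pos in enumerate(_methyl_hydrogens(c3, n)):
        atoms.append(_atom(f"H3{k}", "H", pos, Hybridization.NONE, "H.soft"))
        bonds.append(("C3", f"H3{k}", 1.0))
    mol = MoleculeGraph(atoms=atoms, bonds=bonds)
    for pos in _lone_pairs(o, c2, np.array([0.0, 0.0, 1.0])):
        mol.aips.append(AIP(position=pos, epsilon=-7.2, fraction=1.0,
                            aip_class=AipClass.LONE_PAIR, parent_atom_id="O1"))
    d = hn - n
    d /= np.linalg.norm(d)
    mol.aips.append(AIP(position=hn + 1.1 * d, epsilon=2.6, fraction=1.0,
                        aip_class=AipClass.POLAR_H, parent_atom_id="HN1"))
    mol.aips.append(AIP(position=n + np.array([0.0, 0.0, 1.6]), epsilon=-0.4,
                        fraction=0.5, aip_class=AipClass.PI_SITE,
                        parent_atom_id="N1"))
    _add_ch_aips(mol, [f"H3{k}" for k in range(3)], 0.3)
    return mol


def _methanol_graph() -> MoleculeGraph:
    c = np.zeros(3)
    o = np.array([1.43, 0.0, 0.0])
    h = o + 0.96 * np.array([math.cos(math.radians(108.0)) + 1.0,
                             math.sin(math.radians(108.0)), 0.0]) / np.linalg.norm(
        np.array([math.cos(math.radians(108.0)) + 1.0, math.sin(math.radians(108.0)), 0.0]))
    atoms = [_atom("C1", "C", c, Hybridization.SP3, "C.3"),
             _atom("O1", "O", o, Hybridization.SP3, "O.3.alcohol"),
             _atom("HO1", "H", h, Hybridization.NONE, "H.O")]
    bonds = [("C1", "O1", 1.0), ("O1", "HO1", 1.0)]
    for k, pos in enumerate(_methyl_hydrogens(c, o)):
        atoms.append(_atom(f"H1{k}", "H", pos, Hybridization.NONE, "H.soft"))
        bonds.append(("C1", f"H1{k}", 1.0))
    mol = MoleculeGraph(atoms=atoms, bonds=bonds)
    for pos in _lone_pairs(o, (c + h) / 2.0, np.array([0.0, 0.0, 1.0])):
        mol.aips.append(AIP(position=pos, epsilon=-5.5, fraction=1.0,
                            aip_class=AipClass.LONE_PAIR, parent_atom_id="O1"))
    d = h - o
    d /= np.linalg.norm(d)
    mol.aips.append(AIP(position=h + 1.1 * d, epsilon=3.7, fraction=1.0,
                        aip_class=AipClass.POLAR_H, parent_atom_id="HO1"))
    _add_ch_aips(mol, [f"H1{k}" for k in range(3)], 0.4)
    return mol


def _thioether_graph() -> MoleculeGraph:
    s = np.zeros(3)
    c1 = np.array([-1.45, 1.05, 0.0])
    c2 = np.array([1.45, 1.05, 0.0])
    atoms = [_atom("S1", "S", s, Hybridization.SP3, "S.3"),
             _atom("C1", "C", c1, Hybridization.SP3, "C.3"),
             _atom("C2", "C", c2, Hybridization.SP3, "C.3")]
    bonds = [("S1", "C1", 1.0), ("S1", "C2", 1.0)]
    for cid, cpos in (("C1", c1), ("C2", c2)):
        for k, pos in enumerate(_methyl_hydrogens(cpos, s)):
            hid = f"H{cid}{k}"
            atoms.append(_atom(hid, "H", pos, Hybridization.NONE, "H.soft"))
            bonds.append((cid, hid, 1.0))
    mol = MoleculeGraph(atoms=atoms, bonds=bonds)
    for pos in _lone_pairs(s, (c1 + c2) / 2.0, np.array([0.0, 0.0, 1.0]),
                           dist=1.7, half_angle=45.0):
        mol.aips.append(AIP(position=pos, epsilon=-3.3, fraction=1.0,
                            aip_class=AipClass.LONE_PAIR, parent_atom_id="S1"))
    _add_ch_aips(mol, [f"HC1{k}" for k in range(3)] + [f"HC2{k}" for k in range(3)], 0.3)
    return mol


def _benzene_graph() -> MoleculeGraph:
    atoms, bonds = [], []
    mol_aips = []
    for k in range(6):
        ang = math.pi * k / 3.0
        cpos = 1.39 * np.array([math.cos(ang), math.sin(ang), 0.0])
        hpos = 2.48 * np.array([math.cos(ang), math.sin(ang), 0.0])
        atoms.append(_atom(f"C{k}", "C", cpos, Hybridization.AROMATIC, "C.ar"))
        atoms.append(_atom(f"H{k}", "H", hpos, Hybridization.NONE, "H.soft"))
        bonds.append((f"C{k}", f"C{(k+1) % 6}", 1.5))
        bonds.append((f"C{k}", f"H{k}", 1.0))
        for s in (+1.0, -1.0):
            mol_aips.append(AIP(position=cpos + np.array([0.0, 0.0, 1.8 * s]),
                                epsilon=-1.5, fraction=0.5,
                                aip_class=AipClass.PI_SITE, parent_atom_id=f"C{k}"))
    mol = MoleculeGraph(atoms=atoms, bonds=bonds, aips=mol_aips)
    _add_ch_aips(mol, [f"H{k}" for k in range(6)], 1.0)
    return mol


def _ethanol_graph() -> MoleculeGraph:
    c1 = np.zeros(3)
    c2 = np.array([1.54, 0.0, 0.0])
    o = c2 + np.array([0.48, 1.35, 0.0])
    h = o + np.array([0.95, 0.2, 0.0])
    atoms = [_atom("C1", "C", c1, Hybridization.SP3, "C.3"),
             _atom("C2", "C", c2, Hybridization.SP3, "C.3"),
             _atom("O1", "O", o, Hybridization.SP3, "O.3.alcohol"),
             _atom("HO1", "H", h, Hybridization.NONE, "H.O")]
    bonds = [("C1", "C2", 1.0), ("C2", "O1", 1.0), ("O1", "HO1", 1.0)]
    for k, pos in enumerate(_methyl_hydrogens(c1, c2)):
        atoms.append(_atom(f"H1{k}", "H", pos, Hybridization.NONE, "H.soft"))
        bonds.append(("C1", f"H1{k}", 1.0))
    # two methylene hydrogens on C2
    axis = (o - c1)
    u1, u2 = _orthonormal(axis)
    for k, s in enumerate((+1.0, -1.0)):
        pos = c2 + 1.09 * (0.35 * u1 + s * 0.93 * u2) / np.linalg.norm(0.35 * u1 + s * 0.93 * u2)
        atoms.append(_atom(f"H2{k}", "H", pos, Hybridization.NONE, "H.soft"))
        bonds.append(("C2", f"H2{k}", 1.0))
    mol = MoleculeGraph(atoms=atoms, bonds=bonds)
    for pos in _lone_pairs(o, (c2 + h) / 2.0, np.array([0.0, 0.0, 1.0])):
        mol.aips.append(AIP(position=pos, epsilon=-5.1, fraction=1.0,
                            aip_class=AipClass.LONE_PAIR, parent_atom_id="O1"))
    d = h - o
    d /= np.linalg.norm(d)
    mol.aips.append(AIP(position=h + 1.1 * d, epsilon=3.7, fraction=1.0,
                        aip_class=AipClass.POLAR_H, parent_atom_id="HO1"))
    _add_ch_aips(mol, [f"H1{k}" for k in range(3)] + ["H20", "H21"], 0.4)
    return mol


def make_toy_fragment_library(seed: int = 0) -> list[FragmentRecord]:
    """Small-molecule fragments with hand-placed AIPs and fitted weights.

    Contains an amide (backbone surrogate), an alcohol, a thioether and an
    aromatic ring, plus an ethanol/methanol pair engineered to overlap on
    alcohol-containing targets so that largest-first precedence is
    exercised.  ``seed`` applies a tiny rigid jitter so generated
    libraries differ between seeds without changing topology.
    """
    rng = np.random.default_rng(seed)
    frags = [
        fragment_from_molecule("n-methylacetamide", _nma_graph()),
        fragment_from_molecule("ethanol", _ethanol_graph()),
        fragment_from_molecule("benzene", _benzene_graph()),
        fragment_from_molecule("n-methylformamide", _nmf_graph()),
        fragment_from_molecule("dimethyl-sulfide", _thioether_graph()),
        fragment_from_molecule("methanol", _methanol_graph()),
    ]
    shift = rng.normal(scale=0.01, size=3)
    for f in frags:
        for a in f.graph.atoms:
            a.coords = a.coords + shift
        for p in f.graph.aips:
            p.position = p.position + shift
    # refit so stored weights match the jittered geometry exactly
    return [fragment_from_molecule(f.fragment_id, f.graph) for f in frags]


def make_backbone_chain(n_residues: int = 1) -> MoleculeGraph:
    """A capped oligoglycine backbone: CH3-CO-NH-(CH2-CO-NH)_n-CH3.

    With n_residues=1 this is the classic "dipeptide backbone" diamide
    used to demonstrate fragment matching of the amide unit.
    """
    atoms: list[AtomSite] = []
    bonds: list[tuple[str, str, float]] = []
    step = np.array([2.45, 0.0, 0.0])
    zig = np.array([0.0, 1.0, 0.0])

    c_prev = np.array([-1.52, 0.35, 0.0])
    atoms.append(_atom("CT0", "C", c_prev, Hybridization.SP3, "C.3"))
    for k, pos in enumerate(_methyl_hydrogens(c_prev, c_prev + step * 0.6)):
        atoms.append(_atom(f"HT0{k}", "H", pos, Hybridization.NONE, "H.soft"))
        bonds.append(("CT0", f"HT0{k}", 1.0))
    prev_c_id = "CT0"
    origin = np.zeros(3)
    for r in range(n_residues + 1):
        base = origin + r * step
        sign = 1.0 if r % 2 == 0 else -1.0
        cc = base
        o = base + np.array([0.45, 1.1 * sign, 0.0])
        n = base + np.array([1.25, -0.65 * sign, 0.0])
        hn = n + np.array([-0.25, -0.95 * sign, 0.0])
        atoms += [_atom(f"C{r}", "C", cc, Hybridization.SP2, "C.2"),
                  _atom(f"O{r}", "O", o, Hybridization.SP2, "O.2.am"),
                  _atom(f"N{r}", "N", n, Hybridization.SP2, "N.pl3.am"),
                  _atom(f"HN{r}", "H", hn, Hybridization.NONE, "H.N")]
        bonds += [(prev_c_id, f"C{r}", 1.0), (f"C{r}", f"O{r}", 2.0),
                  (f"C{r}", f"N{r}", 1.0), (f"N{r}", f"HN{r}", 1.0)]
        if r < n_residues:
            ca = n + np.array([1.3, 0.75 * sign, 0.0])
            atoms.append(_atom(f"CA{r}", "C", ca, Hybridization.SP3, "C.3"))
            bonds.append((f"N{r}", f"CA{r}", 1.0))
            u1, u2 = _orthonormal(step)
            for k, s in enumerate((+1.0, -1.0)):
                pos = ca + 1.09 * (0.3 * zig * sign + s * np.array([0.0, 0.0, 1.0]))
                atoms.append(_atom(f"HA{r}{k}", "H", pos, Hybridization.NONE, "H.soft"))
                bonds.append((f"CA{r}", f"HA{r}{k}", 1.0))
            prev_c_id = f"CA{r}"
        else:
            ct = n + np.array([1.3, 0.75 * sign, 0.0])
            atoms.append(_atom("CTN", "C", ct, Hybridization.SP3, "C.3"))
            bonds.append((f"N{r}", "CTN", 1.0))
            for k, pos in enumerate(_methyl_hydrogens(ct, n)):
                atoms.append(_atom(f"HTN{k}", "H", pos, Hybridization.NONE, "H.soft"))
                bonds.append(("CTN", f"HTN{k}", 1.0))
    return MoleculeGraph(atoms=atoms, bonds=bonds)
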