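"""Identify interacting AIP pairs in a protein-ligand complex.

The stepwise analysis: (1) attribute a solvent-accessible surface patch
to every AIP and discard points exposed enough to stay solvated;
(2) identify intermolecular H-bonds from donor/acceptor heavy-atom and
AIP distances; (3) list all remaining cross-molecule AIP pairs closer
than the contact cutoff and solve a maximum-cardinality,
minimum-total-distance bipartite pairing over them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .aip_core import (
    AIP,
    AipClass,
    BONDI_RADII,
    Constants,
    ContactRecord,
    DEFAULT_CONSTANTS,
    MoleculeGraph,
)

__all__ = [
    "CandidatePair",
    "compute_aip_sasa",
    "filter_solvent_exposed",
    "find_hbond_contacts",
    "make_candidate_pairs",
    "pair_remaining_aips",
    "write_contact_table",
]


@dataclass
class CandidatePair:
    ligand_aip: AIP
    protein_aip: AIP
    distance: float
    contact_type: str = "nonpolar"

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


# ---------------------------------------------------------------------------
# Per-AIP solvent-accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere sampling (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def compute_aip_sasa(protein: MoleculeGraph, ligand: MoleculeGraph,
                     probe_radius: float = DEFAULT_CONSTANTS.probe_radius,
                     n_points: int = 960) -> None:
    """Fill ``aip.sasa`` for every AIP of both molecules, in place.

    Shrake-Rupley style: each AIP-bearing atom's solvent-accessible sphere
    (r_vdW + probe) is point-sampled; points not buried inside any other
    atom's accessible sphere are accessible, and each accessible point is
    attributed to the nearest AIP of that atom.  The AIP's SASA is its
    share of the accessible area.  All atoms of the complex act as
    occluders.
    """
    molecules = [protein, ligand]
    atoms = [a for m in molecules for a in m.atoms]
    for a in atoms:
        if a.element not in BONDI_RADII:
            raise ValueError(f"no van der Waals radius for element {a.element!r} "
                             f"(atom {a.atom_id!r})")
    coords = np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)
    radii = np.array([BONDI_RADII[a.element] + probe_radius for a in atoms])
    tree = cKDTree(coords)
    unit = _sphere_points(n_points)
    id_to_row: dict[int, int] = {}
    for row, a in enumerate(atoms):
        id_to_row.setdefault(id(a), row)

    for mol in molecules:
        by_atom: dict[str, list[AIP]] = {}
        for p in mol.aips:
            by_atom.setdefault(p.parent_atom_id, []).append(p)
        index = mol._index()
        for atom_id, aips in by_atom.items():
            atom = index[atom_id]
            row = id_to_row[id(atom)]
            r = radii[row]
            pts = coords[row] + r * unit
            neighbours = [j for j in tree.query_ball_point(coords[row], r + radii.max())
                          if j != row]
            accessible = np.ones(len(pts), dtype=bool)
            for j in neighbours:
                d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
                accessible &= d2 > radii[j] ** 2
            area_per_point = 4.0 * np.pi * r * r / n_points
            aip_pos = np.array([p.position for p in aips])
            for p in aips:
                p.sasa = 0.0
            if accessible.any():
                d = np.linalg.norm(pts[accessible, None, :] - aip_pos[None, :, :],
                                   axis=2)
                nearest = np.argmin(d, axis=1)
                counts = np.bincount(nearest, minlength=len(aips))
                for p, c in zip(aips, counts):
                    p.sasa = float(c) * area_per_point


def filter_solvent_exposed(aips: list[AIP],
                           sasa_cutoff: float = DEFAULT_CONSTANTS.sasa_cutoff
                           ) -> list[AIP]:
    """Keep AIPs whose surface patch is small enough to be desolvated on
    binding; SASA strictly greater than the cutoff means the point stays
    solvated and is eliminated."""
    for p in aips:
        if p.sasa is None:
            raise ValueError("SASA not computed before filtering")
    return [p for p in aips if p.sasa <= sasa_cutoff]


# ---------------------------------------------------------------------------
# H-bond identification
# ---------------------------------------------------------------------------

def _donor_heavy_atom(mol: MoleculeGraph, aip: AIP):
    """Heavy atom behind a polar-H AIP: the atom bonded to the parent H."""
    parent = mol.atom(aip.parent_atom_id)
    if parent.element != "H":
        return parent
    for nb in mol.neighbors(parent.atom_id):
        site = mol.atom(nb)
        if site.element != "H":
            return site
    return parent


def find_hbond_contacts(protein: MoleculeGraph, ligand: MoleculeGraph,
                        protein_aips: list[AIP] | None = None,
                        ligand_aips: list[AIP] | None = None,
                        constants: Constants = DEFAULT_CONSTANTS
                        ) -> list[ContactRecord]:
    """Intermolecular H-bonds as polar-H / lone-pair AIP pairs.

    A pair qualifies when the donor and acceptor heavy atoms are closer
    than the heavy-atom cutoff and the two AIPs are closer than the AIP
    cutoff.  Pairs are accepted greedily by ascending AIP distance (ties:
    ligand atom id then protein atom id) with every AIP used at most once.
    """
    protein_aips = protein.aips if protein_aips is None else protein_aips
    ligand_aips = ligand.aips if ligand_aips is None else ligand_aips
    candidates = []
    for lp, lmol, pp, pmol in _donor_acceptor_pairs(
            ligand, protein, ligand_aips, protein_aips):
        heavy_l = _donor_heavy_atom(lmol, lp) if lp.aip_class is AipClass.POLAR_H \
            else lmol.atom(lp.parent_atom_id)
        heavy_p = _donor_heavy_atom(pmol, pp) if pp.aip_class is AipClass.POLAR_H \
            else pmol.atom(pp.parent_atom_id)
        heavy_d = float(np.linalg.norm(heavy_l.coords - heavy_p.coords))
        aip_d = float(np.linalg.norm(lp.position - pp.position))
        if heavy_d < constants.hbond_heavy_cutoff and aip_d < constants.hbond_aip_cutoff:
            candidates.append((aip_d, lp.parent_atom_id, pp.parent_atom_id, lp, pp))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[int] = set()
    contacts = []
    for aip_d, _, _, lp, pp in candidates:
        if id(lp) in used or id(pp) in used:
            continue
        used.update((id(lp), id(pp)))
        contacts.append(ContactRecord(
            ligand_aip=lp, protein_aip=pp, contact_type="hbond",
            distance=aip_d, f_effective=min(lp.fraction, pp.fraction)))
    return contacts


def _donor_acceptor_pairs(ligand, protein, ligand_aips, protein_aips):
    l_don = [p for p in ligand_aips if p.aip_class is AipClass.POLAR_H]
    l_acc = [p for p in ligand_aips if p.aip_class is AipClass.LONE_PAIR]
    p_don = [p for p in protein_aips if p.aip_class is AipClass.POLAR_H]
    p_acc = [p for p in protein_aips if p.aip_class is AipClass.LONE_PAIR]
    for lp in l_don:
        for pp in p_acc:
            yield lp, ligand, pp, protein
    for lp in l_acc:
        for pp in p_don:
            yield lp, ligand, pp, protein


# ---------------------------------------------------------------------------
# General pairing
# ---------------------------------------------------------------------------

def make_candidate_pairs(ligand_aips: list[AIP], protein_aips: list[AIP],
                         contact_cutoff: float = DEFAULT_CONSTANTS.contact_cutoff
                         ) -> list[CandidatePair]:
    """All cross-molecule AIP pairs strictly closer than the cutoff."""
    out = []
    for lp in ligand_aips:
        for pp in protein_aips:
            d = float(np.linalg.norm(lp.position - pp.position))
            if d < contact_cutoff:
                out.append(CandidatePair(ligand_aip=lp, protein_aip=pp, distance=d))
    return out


def pair_remaining_aips(candidates: list[CandidatePair]) -> list[ContactRecord]:
    """Maximum-cardinality, then minimum-total-distance bipartite pairing.

    Implemented as a min-cost assignment where every candidate edge costs
    (distance - M) with M far larger than any achievable total distance,
    so cardinality strictly dominates the objective.
    """
    if not candidates:
        return []
    lig = sorted({id(c.ligand_aip): c.ligand_aip for c in candidates}.values(),
                 key=lambda p: (p.parent_atom_id, tuple(p.position)))
    pro = sorted({id(c.protein_aip): c.protein_aip for c in candidates}.values(),
                 key=lambda p: (p.parent_atom_id, tuple(p.position)))
    li = {id(p): i for i, p in enumerate(lig)}
    pi = {id(p): i for i, p in enumerate(pro)}
    M = 1e6
    cost = np.zeros((len(lig), len(pro)))
    edge: dict[tuple[int, int], CandidatePair] = {}
    for c in candidates:
        key = (li[id(c.ligand_aip)], pi[id(c.protein_aip)])
        if key not in edge or c.distance < edge[key].distance:
            edge[key] = c
            cost[key] = c.distance - M
    rows, cols = linear_sum_assignment(cost)
    contacts = []
    for r, c in zip(rows, cols):
        pair = edge.get((r, c))
        if pair is None:
            continue  # dummy assignment, not a real candidate
        contacts.append(ContactRecord(
            ligand_aip=pair.ligand_aip, protein_aip=pair.protein_aip,
            contact_type="nonpolar", distance=pair.distance,
            f_effective=min(pair.ligand_aip.fraction, pair.protein_aip.fraction)))
    contacts.sort(key=lambda c: (c.ligand_aip.parent_atom_id,
                                 c.protein_aip.parent_atom_id))
    return contacts


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def read_contact_table(source):
    """Read a contact table TSV into a DataFrame (as written by
    :func:`write_contact_table`)."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t", keep_default_na=False,
                     dtype={"contact_type": str})
    required = {"contact_type", "ligand_aip_value", "protein_aip_value",
                "f", "ddG_kJ_per_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contact table missing columns: {sorted(missing)}")
    return df


def load_reference_contact_table():
    """The shipped per-contact reference table for the 2W4X complex
    (transcribed published values; used for desk-scale checks and for the
    water calibration provenance)."""
    from importlib import resources

    ref = resources.files("aipmap.data").joinpath("aip_contacts_2w4x.tsv")
    with ref.open("r") as fh:
        return read_contact_table(fh)


def write_contact_table(contacts: list[ContactRecord], protein: MoleculeGraph,
                        ligand: MoleculeGraph, path=None) -> str:
    """Contact table TSV: type, atom types, AIP values, f and ddG."""
    header = ("contact_type\tligand_atom_type\tprotein_atom_type\t"
              "ligand_aip_value\tprotein_aip_value\tf\tddG_kJ_per_mol")
    lines = [header]
    for c in contacts:
        lt = ligand.atom(c.ligand_aip.parent_atom_id).sybyl_type or "?"
        pt = protein.atom(c.protein_aip.parent_atom_id).sybyl_type or "?"
        ctype = "H-bond" if c.contact_type == "hbond" else ""
        ddg = "" if c.ddG is None else f"{c.ddG:.1f}"
        lines.append(f"{ctype}\t{lt}\t{pt}\t{c.ligand_aip.epsilon:.1f}\t"
                     f"{c.protein_aip.epsilon:.1f}\t{c.f_effective}\t{ddg}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
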