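"""Read footprinted ligand AIP descriptions and project them onto a pose.

Ligand AIPs come from an external electronic-structure footprinting step
and arrive as CML with the AIP extension.  Projection re-expresses every
AIP as a virtual site on the footprinted geometry (anchor atoms plus
weights) and evaluates it on the posed coordinates, so each site moves
rigidly with its local anchor frame.  Epsilon and f are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx

from .aip_core import AIP, MoleculeGraph, read_cml, AIP_NS
from .fragment_matching import fit_virtual_site_weights, place_virtual_site, \
    select_anchor_atoms

__all__ = ["LigandAipDocument", "read_ligand_cml", "project_ligand_aips"]


@dataclass
class LigandAipDocument:
    molecule: MoleculeGraph
    provenance: str = ""


def read_ligand_cml(path) -> LigandAipDocument:
    """Parse a ligand CML document carrying the AIP extension.

    A document without any AIP extension elements is rejected: a ligand
    description with no interaction sites is a data error, not an empty
    result.
    """
    mol = read_cml(path)
    if not mol.aips:
        raise ValueError(
            f"CML document {path!r} carries no AIP extension elements "
            f"(namespace {AIP_NS}); a footprinted ligand description is required")
    for k, p in enumerate(mol.aips):
        if not np.isfinite(p.epsilon):
            raise ValueError(f"AIP #{k} has non-finite epsilon")
    return LigandAipDocument(molecule=mol, provenance="")


def _element_multigraph(m: MoleculeGraph) -> nx.Graph:
    g = nx.Graph()
    for a in sorted(m.atoms, key=lambda s: s.atom_id):
        g.add_node(a.atom_id, element=a.element)
    for a, b, order in m.bonds:
        g.add_edge(a, b, order=order)
    return g


def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD between point sets after optimal rigid superposition."""
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    diff = Pc @ R - Qc
    return float(np.sqrt((diff ** 2).sum() / len(P)))


def _find_correspondence(doc: MoleculeGraph, pose: MoleculeGraph) -> dict[str, str]:
    """Graph isomorphism doc -> pose on (element, bond order).

    Symmetric ligands admit several automorphic mappings; the one with the
    smallest RMSD after optimal superposition is chosen (ties broken
    lexicographically), so the projection is deterministic.
    """
    gd, gp = _element_multigraph(doc), _element_multigraph(pose)
    # poses read from PDB carry no bond orders (all 1.0); compare orders
    # only when both graphs carry explicit ones
    pose_has_orders = any(abs(d.get("order", 1.0) - 1.0) > 1e-9
                          for _, _, d in gp.edges(data=True))
    doc_has_orders = any(abs(d.get("order", 1.0) - 1.0) > 1e-9
                         for _, _, d in gd.edges(data=True))
    use_orders = pose_has_orders and doc_has_orders
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        gp, gd,
        node_match=lambda p, d: p["element"] == d["element"],
        edge_match=(lambda p, d: abs(p.get("order", 1.0) - d.get("order", 1.0)) < 0.25)
        if use_orders else None)
    mappings = []
    for mapping in matcher.isomorphisms_iter():
        mappings.append({d: p for p, d in mapping.items()})
        if len(mappings) >= 5000:  # enough for any chemically relevant symmetry
            break
    if not mappings:
        detail = _first_mismatch(doc, pose)
        raise ValueError(f"ligand document and pose are not isomorphic: {detail}")
    doc_ids = sorted(a.atom_id for a in doc.atoms)
    P = np.array([doc.atom(i).coords for i in doc_ids])

    def score(mp):
        Q = np.array([pose.atom(mp[i]).coords for i in doc_ids])
        return (round(_kabsch_rmsd(P, Q), 9), tuple(mp[i] for i in doc_ids))

    return min(mappings, key=score)


def _first_mismatch(doc: MoleculeGraph, pose: MoleculeGraph) -> str:
    def census(m):
        from collections import Counter
        return Counter((a.element, len(m.neighbors(a.atom_id))) for a in m.atoms)

    cd, cp = census(doc), census(pose)
    for key in sorted(set(cd) | set(cp), key=str):
        if cd.get(key, 0) != cp.get(key, 0):
            el, deg = key
            return (f"atom environment ({el}, degree {deg}) occurs "
                    f"{cd.get(key, 0)}x in the document but {cp.get(key, 0)}x in the pose")
    return "same atom-environment census but no consistent bond mapping"


def project_ligand_aips(doc: LigandAipDocument, pose: MoleculeGraph) -> MoleculeGraph:
    """Transfer the document's AIPs onto the posed ligand geometry.

    For each AIP, anchor atoms and virtual-site weights are fitted on the
    footprinted geometry and evaluated on the corresponding pose atoms.
    The returned graph is a copy of ``pose`` with AIPs attached.
    """
    src = doc.molecule
    mapping = _find_correspondence(src, pose)
    out = pose.copy()
    out.aips = []
    for k, p in enumerate(src.aips):
        anchors = select_anchor_atoms(src, p.position)
        w = fit_virtual_site_weights([src.atom(a).coords for a in anchors],
                                     p.position, context=f"ligand AIP #{k}")
        pos = place_virtual_site([out.atom(mapping[a]).coords for a in anchors], w)
        out.aips.append(AIP(position=pos, epsilon=p.epsilon, fraction=p.fraction,
                            aip_class=p.aip_class,
                            parent_atom_id=mapping[p.parent_atom_id]))
    return out
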