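"""Assign AIPs to macromolecules by fragment subgraph matching.

A macromolecule built from repeating chemical building blocks (a protein)
inherits its surface interaction points from a library of small molecules
that were characterised once, in an extended conformation.  Each library
fragment stores its AIPs as *virtual sites*: a site's position is expressed
relative to three anchor atoms,

    r_AIP = r1 + w12*r12 + w13*r13 + w_cross*(r12 x r13)

where atom 1 is the atom closest to the AIP and atoms 2 and 3 are the two
atoms the fewest bonds away from atom 1.  Because the weights are
coordinate-frame independent, the same site can be re-placed on any
matched copy of the fragment geometry.

Fragments are complete molecules, so the subgraph matcher is modified:
a fragment C-H hydrogen may match a target *carbon* that is sp3 or bonded
to an sp3 carbon.  Such hydrogens stand in for the bonds that continue
into the macromolecule (fragments are built so that the truncated
neighbour is always a carbon), and the carbons they match receive no AIPs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .aip_core import (
    AIP,
    AipClass,
    AtomSite,
    Hybridization,
    MoleculeGraph,
)
from lxml import etree

__all__ = [
    "AipTemplate",
    "FragmentRecord",
    "MatchResult",
    "fit_virtual_site_weights",
    "place_virtual_site",
    "select_anchor_atoms",
    "fragment_from_molecule",
    "match_fragment",
    "build_macromolecule_aips",
    "load_fragment_library",
    "write_fragment_library",
    "write_aip_pdb",
]

_DEGENERACY_TOL = 1e-10
_ELEMENT_PRIORITY = {"C": 0, "N": 1, "O": 2, "S": 3}


class DegenerateAnchorError(ValueError):
    """Anchor triple is (near-)collinear; virtual-site frame undefined."""


# ---------------------------------------------------------------------------
# Virtual-site geometry
# ---------------------------------------------------------------------------

def fit_virtual_site_weights(anchor_coords, aip_position, *, context: str = ""):
    """Solve for (w12, w13, w_cross) reproducing ``aip_position``.

    ``anchor_coords`` are the positions of anchor atoms 1, 2 and 3.  The
    offset (aip - r1) is expanded in the basis {r12, r13, r12 x r13}; the
    3x3 system is solved directly.  Raises :class:`DegenerateAnchorError`
    when the anchors are collinear.
    """
    r1, r2, r3 = (np.asarray(c, dtype=float) for c in anchor_coords)
    r12, r13 = r2 - r1, r3 - r1
    cross = np.cross(r12, r13)
    if np.dot(cross, cross) < _DEGENERACY_TOL:
        raise DegenerateAnchorError(
            f"collinear anchor geometry{f' ({context})' if context else ''}")
    basis = np.column_stack([r12, r13, cross])
    w = np.linalg.solve(basis, np.asarray(aip_position, dtype=float) - r1)
    return float(w[0]), float(w[1]), float(w[2])


def place_virtual_site(anchor_coords, weights) -> np.ndarray:
    """Forward evaluation: r1 + w12*r12 + w13*r13 + w_cross*(r12 x r13)."""
    r1, r2, r3 = (np.asarray(c, dtype=float) for c in anchor_coords)
    w12, w13, wc = weights
    r12, r13 = r2 - r1, r3 - r1
    return r1 + w12 * r12 + w13 * r13 + wc * np.cross(r12, r13)


def _bond_distances(graph: MoleculeGraph, start: str) -> dict[str, int]:
    dist = {start: 0}
    q = deque([start])
    while q:
        cur = q.popleft()
        for nb in graph.neighbors(cur):
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                q.append(nb)
    return dist


def select_anchor_atoms(graph: MoleculeGraph, aip_position) -> tuple[str, str, str]:
    """Choose the anchor triple for an AIP on ``graph``.

    Atom 1 is the atom closest in space to the AIP; atoms 2 and 3 are the
    two atoms the fewest bonds away from atom 1, ties broken by
    (bond distance, element priority C<N<O<S, atom id), skipping choices
    that leave the frame degenerate.
    """
    pos = np.asarray(aip_position, dtype=float)
    a1 = min(graph.atoms, key=lambda a: (float(np.linalg.norm(a.coords - pos)), a.atom_id))
    dist = _bond_distances(graph, a1.atom_id)
    cands = [a for a in graph.atoms if a.atom_id != a1.atom_id and a.atom_id in dist]

    def key(a: AtomSite):
        return (dist[a.atom_id],
                _ELEMENT_PRIORITY.get(a.element, 4 if a.element != "H" else 5),
                a.atom_id)

    cands.sort(key=key)
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            a2, a3 = cands[i], cands[j]
            cross = np.cross(a2.coords - a1.coords, a3.coords - a1.coords)
            if np.dot(cross, cross) >= _DEGENERACY_TOL:
                return a1.atom_id, a2.atom_id, a3.atom_id
    raise DegenerateAnchorError(
        f"no non-collinear anchor pair found for AIP near atom {a1.atom_id!r}")


@dataclass
class AipTemplate:
    """An AIP of a library fragment, stored as a fitted virtual site."""

    epsilon: float
    fraction: float
    aip_class: AipClass
    parent_atom_id: str
    anchor_atoms: tuple[str, str, str]
    weights: tuple[float, float, float]


@dataclass
class FragmentRecord:
    """A footprinted library molecule with its virtual-site AIP templates."""

    fragment_id: str
    graph: MoleculeGraph
    aip_templates: list[AipTemplate] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.graph.atoms)


@dataclass
class MatchResult:
    fragment_id: str
    atom_map: dict[str, str]  # fragment atom_id -> target atom_id
    h_to_c_matches: list[tuple[str, str]] = field(default_factory=list)


def fragment_from_molecule(fragment_id: str, graph: MoleculeGraph) -> FragmentRecord:
    """Build a FragmentRecord by fitting virtual-site weights to the
    fragment's own AIP geometry."""
    templates = []
    for k, p in enumerate(graph.aips):
        anchors = select_anchor_atoms(graph, p.position)
        coords = [graph.atom(a).coords for a in anchors]
        w = fit_virtual_site_weights(coords, p.position,
                                     context=f"{fragment_id} AIP #{k}")
        templates.append(AipTemplate(
            epsilon=p.epsilon, fraction=p.fraction, aip_class=p.aip_class,
            parent_atom_id=p.parent_atom_id, anchor_atoms=anchors, weights=w))
    return FragmentRecord(fragment_id=fragment_id, graph=graph, aip_templates=templates)


# ---------------------------------------------------------------------------
# Modified subgraph matching
# ---------------------------------------------------------------------------

def _to_nx(graph: MoleculeGraph, *, as_target: bool) -> nx.Graph:
    g = nx.Graph()
    index = graph._index()
    for a in sorted(graph.atoms, key=lambda s: s.atom_id):
        g.add_node(a.atom_id, element=a.element, hyb=a.hybridization)
    for a, b, order in graph.bonds:
        g.add_edge(a, b, order=order)
    if as_target:
        # flag carbons that an H may match: sp3, or bonded to an sp3 carbon
        for aid in g.nodes:
            site = index[aid]
            ok = False
            if site.element == "C":
                if site.hybridization is Hybridization.SP3:
                    ok = True
                else:
                    ok = any(index[nb].element == "C"
                             and index[nb].hybridization is Hybridization.SP3
                             for nb in g.neighbors(aid))
            g.nodes[aid]["h_matchable"] = ok
    else:
        for aid in g.nodes:
            site = index[aid]
            g.nodes[aid]["ch_hydrogen"] = (
                site.element == "H"
                and any(index[nb].element == "C" for nb in g.neighbors(aid)))
    return g


def _node_match(t_attrs: dict, f_attrs: dict) -> bool:
    fe, te = f_attrs["element"], t_attrs["element"]
    if fe == "H":
        if te == "H":
            return True
        return bool(f_attrs.get("ch_hydrogen")) and te == "C" \
            and bool(t_attrs.get("h_matchable"))
    if fe != te:
        return False
    fh, th = f_attrs["hyb"], t_attrs["hyb"]
    if fh is Hybridization.NONE or th is Hybridization.NONE:
        return True
    return fh == th


def match_fragment(fragment: MoleculeGraph, target: MoleculeGraph,
                   assigned_atoms: set[str] | None = None,
                   fragment_id: str = "") -> list[MatchResult]:
    """All monomorphic embeddings of ``fragment`` into ``target``.

    Heavy atoms must agree in element and hybridization (aromatic flags
    included); fragment hydrogens bonded to carbon may also match target
    carbons that are sp3 or bonded to an sp3 carbon.  Target atoms in
    ``assigned_atoms`` never participate.  Results are canonically ordered
    by the sorted target atom ids of the match.
    """
    assigned_atoms = assigned_atoms or set()
    tg = _to_nx(target, as_target=True)
    tg.remove_nodes_from([n for n in list(tg.nodes) if n in assigned_atoms])
    fg = _to_nx(fragment, as_target=False)
    if fg.number_of_nodes() == 0 or fg.number_of_nodes() > tg.number_of_nodes():
        return []
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        tg, fg, node_match=_node_match)
    felem = {a.atom_id: a.element for a in fragment.atoms}
    telem = {a.atom_id: a.element for a in target.atoms}
    seen: set[tuple] = set()
    results: list[MatchResult] = []
    for mapping in matcher.subgraph_monomorphisms_iter():
        atom_map = {f: t for t, f in mapping.items()}
        key = tuple(sorted(atom_map.items()))
        if key in seen:
            continue
        seen.add(key)
        h2c = sorted((f, t) for f, t in atom_map.items()
                     if felem[f] == "H" and telem[t] == "C")
        results.append(MatchResult(fragment_id=fragment_id, atom_map=atom_map,
                                   h_to_c_matches=h2c))
    results.sort(key=lambda r: sorted(r.atom_map.values()))
    return results


# ---------------------------------------------------------------------------
# Iterative greedy cover of a macromolecule
# ---------------------------------------------------------------------------

def build_macromolecule_aips(target: MoleculeGraph,
                             library: list[FragmentRecord],
                             ) -> tuple[MoleculeGraph, list[str]]:
    """Project library AIPs onto ``target`` by iterative greedy matching.

    Largest fragments are matched first; at each round only fragments no
    larger than the region still lacking an AIP description are
    considered.  AIPs are placed with the fitted virtual-site weights
    evaluated on the matched target coordinates.  AIPs are never added to
    atoms that already carry AIPs, nor to carbons matched by a fragment
    C-H hydrogen; matched atoms remain visible to later rounds (adjacent
    fragments overlap at the linking atoms), so a match is applied only
    when it contributes at least one new AIP.  Returns the AIP-decorated
    copy of the target and the ids of atoms no applied match described.
    """
    out = target.copy()
    has_aip: set[str] = {p.parent_atom_id for p in out.aips}
    covered: set[str] = set()
    order = {f.fragment_id: i for i, f in enumerate(library)}
    while True:
        remaining = len(out.atoms) - len(has_aip)
        if remaining <= 0:
            break
        cands = [f for f in library if f.n_atoms <= remaining]
        cands.sort(key=lambda f: (-f.n_atoms, order[f.fragment_id]))
        chosen = None
        for frag in cands:
            for match in match_fragment(frag.graph, out, None, frag.fragment_id):
                h2c_targets = {t for _, t in match.h_to_c_matches}
                additions = [
                    tmpl for tmpl in frag.aip_templates
                    if match.atom_map[tmpl.parent_atom_id] not in h2c_targets
                    and match.atom_map[tmpl.parent_atom_id] not in has_aip]
                if additions:
                    chosen = (match, additions, h2c_targets)
                    break
            if chosen:
                break
        if chosen is None:
            break
        match, additions, _ = chosen
        for tmpl in additions:
            anchor_coords = [out.atom(match.atom_map[a]).coords
                             for a in tmpl.anchor_atoms]
            pos = place_virtual_site(anchor_coords, tmpl.weights)
            out.aips.append(AIP(position=pos, epsilon=tmpl.epsilon,
                                fraction=tmpl.fraction, aip_class=tmpl.aip_class,
                                parent_atom_id=match.atom_map[tmpl.parent_atom_id]))
        has_aip |= {match.atom_map[t.parent_atom_id] for t in additions}
        covered |= set(match.atom_map.values())
    uncovered = sorted(a.atom_id for a in out.atoms if a.atom_id not in covered)
    return out, uncovered


# ---------------------------------------------------------------------------
# Fragment-library XML (virtual-site force-field dialect)
# ---------------------------------------------------------------------------

def write_fragment_library(library: list[FragmentRecord], path=None) -> str:
    root = etree.Element("AipForceField")
    for frag in library:
        fel = etree.SubElement(root, "Fragment", name=frag.fragment_id)
        for a in frag.graph.atoms:
            etree.SubElement(fel, "Atom", id=a.atom_id, element=a.element,
                             hybridization=a.hybridization.value,
                             sybylType=a.sybyl_type,
                             x=f"{a.coords[0]:.8f}", y=f"{a.coords[1]:.8f}",
                             z=f"{a.coords[2]:.8f}")
        for a, b, order in frag.graph.bonds:
            etree.SubElement(fel, "Bond", **{"from": a, "to": b, "order": repr(order)})
        for t in frag.aip_templates:
            etree.SubElement(
                fel, "Aip",
                **{"class": t.aip_class.value, "epsilon": f"{t.epsilon:.6f}",
                   "fraction": repr(t.fraction), "parent": t.parent_atom_id,
                   "atom1": t.anchor_atoms[0], "atom2": t.anchor_atoms[1],
                   "atom3": t.anchor_atoms[2], "w12": f"{t.weights[0]:.12f}",
                   "w13": f"{t.weights[1]:.12f}", "wcross": f"{t.weights[2]:.12f}"})
    text = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_fragment_library(source) -> list[FragmentRecord]:
    """Parse the virtual-site force-field XML into FragmentRecords.

    Each AIP entry must reconstruct its own fragment geometry: placing the
    stored weights on the fragment's anchor coordinates must land on a
    self-consistent position (weights are re-fitted when absent).
    Malformed entries raise with the fragment name and source line.
    """
    if isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    else:
        root = etree.parse(str(source)).getroot()
    library: list[FragmentRecord] = []
    for fel in root.findall("Fragment"):
        name = fel.get("name", "?")
        atoms, bonds, templates = [], [], []
        try:
            for ael in fel.findall("Atom"):
                atoms.append(AtomSite(
                    atom_id=ael.get("id"), element=ael.get("element"),
                    hybridization=Hybridization(ael.get("hybridization", "none")),
                    sybyl_type=ael.get("sybylType", ""),
                    coords=np.array([float(ael.get(k)) for k in "xyz"])))
            for bel in fel.findall("Bond"):
                bonds.append((bel.get("from"), bel.get("to"),
                              float(bel.get("order", "1"))))
            graph = MoleculeGraph(atoms=atoms, bonds=bonds)
            for pel in fel.findall("Aip"):
                anchors = tuple(pel.get(f"atom{i}") for i in (1, 2, 3))
                coords = [graph.atom(a).coords for a in anchors]
                if pel.get("w12") is not None:
                    w = tuple(float(pel.get(k)) for k in ("w12", "w13", "wcross"))
                    pos = place_virtual_site(coords, w)
                else:
                    pos = np.array([float(pel.get(k)) for k in ("x3", "y3", "z3")])
                    w = fit_virtual_site_weights(coords, pos, context=name)
                check = place_virtual_site(coords, w)
                if np.linalg.norm(check - pos) > 1e-6:
                    raise ValueError("weights do not reconstruct the AIP position")
                templates.append(AipTemplate(
                    epsilon=float(pel.get("epsilon")),
                    fraction=float(pel.get("fraction", "1.0")),
                    aip_class=AipClass(pel.get("class", "other")),
                    parent_atom_id=pel.get("parent"),
                    anchor_atoms=anchors, weights=w))
                graph.aips.append(AIP(position=pos, epsilon=templates[-1].epsilon,
                                      fraction=templates[-1].fraction,
                                      aip_class=templates[-1].aip_class,
                                      parent_atom_id=templates[-1].parent_atom_id))
        except Exception as exc:
            line = getattr(fel, "sourceline", "?")
            raise ValueError(
                f"malformed fragment {name!r} (near line {line}): {exc}") from exc
        library.append(FragmentRecord(fragment_id=name, graph=graph,
                                      aip_templates=templates))
    return library


def write_aip_pdb(graph: MoleculeGraph, pdb_path, table_path=None) -> None:
    """Write the molecule plus its AIPs as pseudo-atoms (HETATM, element X)
    and a sidecar TSV with epsilon, f, class and parent atom."""
    from .aip_core import write_pdb

    text = write_pdb(graph).rstrip().rsplit("\n", 1)[0]  # drop END
    lines = [text]
    base = len(graph.atoms)
    for k, p in enumerate(graph.aips, start=1):
        x, y, z = p.position
        lines.append(
            f"HETATM{base + k:>5} {'X' + str(k % 1000):<4} AIP X{1:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{p.fraction:6.2f}{p.epsilon:6.2f}           X")
    lines.append("END")
    with open(pdb_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if table_path is not None:
        with open(table_path, "w") as fh:
            fh.write("aip_index\tepsilon\tfraction\taip_class\tparent_atom\n")
            for k, p in enumerate(graph.aips, start=1):
                fh.write(f"{k}\t{p.epsilon:.4f}\t{p.fraction}\t"
                         f"{p.aip_class.value}\t{p.parent_atom_id}\n")
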