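"""Core domain types for surface-site interaction-point (AIP) modelling.

An AIP is a discrete point on a molecule's van der Waals surface that
encodes the propensity of the underlying ~9 A^2 surface patch for
noncovalent interactions.  Its polarity parameter ``epsilon`` is signed:
positive for H-bond donor / positively polarised sites, negative for
acceptor / negatively polarised sites, so that the free energy of a single
point contact scales with the product ``eps_i * eps_j`` (products < 0 are
attractive).  Sites representing pi-electron density cover a smaller patch
and carry a fractional weight f = 0.5; all other sites have f = 1.

This module holds the data model (atoms, molecular graphs, AIPs, solvent
descriptions), the physical constants and geometric thresholds used by the
rest of the package, structural validation, and CML serialization with a
namespaced AIP extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "AipClass",
    "Hybridization",
    "AIP",
    "AtomSite",
    "MoleculeGraph",
    "SolventModel",
    "Constants",
    "ContactRecord",
    "DEFAULT_CONSTANTS",
    "BONDI_RADII",
    "validate_molecule",
    "write_cml",
    "read_cml",
    "write_pdb",
    "read_pdb",
]

CML_NS = "http://www.xml-cml.org/schema"
AIP_NS = "https://aipmap.dev/ns/aip"
_NSMAP = {"cml": CML_NS, "aip": AIP_NS}


class AipClass(str, Enum):
    """Chemical class of a surface interaction point."""

    LONE_PAIR = "lone_pair"
    PI_SITE = "pi_site"
    CH_DONOR = "ch_donor"
    POLAR_H = "polar_h"
    OTHER = "other"


#: Classes that represent pi-electron density and therefore carry f = 0.5.
PI_DENSITY_CLASSES = frozenset({AipClass.PI_SITE})


class Hybridization(str, Enum):
    SP3 = "sp3"
    SP2 = "sp2"
    SP = "sp"
    AROMATIC = "aromatic"
    NONE = "none"


#: Bondi van der Waals radii in Angstrom, used for surface construction.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

#: Single-bond covalent radii (A) for distance-based bond perception.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Br": 1.20,
    "I": 1.39,
}


@dataclass(frozen=True)
class Constants:
    """Physical constants and geometric thresholds of the contact model.

    Units are kJ/mol for energies, Angstrom for lengths, Kelvin for
    temperature.  ``e_vdw`` is the free energy of a nonpolar van der Waals
    surface contact.  The thresholds drive the stepwise contact analysis:
    AIPs whose solvent-accessible patch exceeds ``sasa_cutoff`` (computed
    with ``probe_radius``) are considered solvated and excluded; H-bonds
    require donor/acceptor heavy atoms closer than ``hbond_heavy_cutoff``
    and paired AIPs closer than ``hbond_aip_cutoff``; all other contacts
    require AIP separations below ``contact_cutoff``.
    """

    e_vdw: float = -5.6
    gas_constant: float = 8.314e-3
    temperature: float = 298.0
    probe_radius: float = 0.35
    sasa_cutoff: float = 9.8
    hbond_heavy_cutoff: float = 3.0
    hbond_aip_cutoff: float = 2.2
    contact_cutoff: float = 1.7

    def __post_init__(self) -> None:
        for name in ("probe_radius", "sasa_cutoff", "hbond_heavy_cutoff",
                     "hbond_aip_cutoff", "contact_cutoff", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


DEFAULT_CONSTANTS = Constants()


@dataclass
class AtomSite:
    """One atom: identity, chemistry and coordinates.

    ``sybyl_type`` uses Sybyl-flavoured labels ("O.2.am", "H.soft",
    "C.ar", ...) for reporting; ``hybridization`` is what the subgraph
    matcher consumes.  Residue fields are PDB provenance and optional for
    ligand atoms.
    """

    atom_id: str
    element: str
    hybridization: Hybridization = Hybridization.NONE
    sybyl_type: str = ""
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    residue_name: str | None = None
    residue_index: int | None = None
    chain_id: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class AIP:
    """A single surface interaction point.

    ``sasa`` (A^2) is unset until the contact engine attributes a surface
    patch to the point.
    """

    position: np.ndarray
    epsilon: float
    fraction: float
    aip_class: AipClass
    parent_atom_id: str
    sasa: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.aip_class = AipClass(self.aip_class)


@dataclass
class MoleculeGraph:
    """A molecule as a labelled graph plus (optionally) its AIPs."""

    atoms: list[AtomSite]
    bonds: list[tuple[str, str, float]]
    aips: list[AIP] = field(default_factory=list)

    def atom(self, atom_id: str) -> AtomSite:
        return self._index()[atom_id]

    def _index(self) -> dict[str, AtomSite]:
        return {a.atom_id: a for a in self.atoms}

    def neighbors(self, atom_id: str) -> list[str]:
        out = []
        for a, b, _ in self.bonds:
            if a == atom_id:
                out.append(b)
            elif b == atom_id:
                out.append(a)
        return out

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def aips_of(self, atom_id: str) -> list[AIP]:
        return [p for p in self.aips if p.parent_atom_id == atom_id]

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(
            atoms=[replace(a, coords=a.coords.copy()) for a in self.atoms],
            bonds=list(self.bonds),
            aips=[replace(p, position=p.position.copy()) for p in self.aips],
        )


@dataclass
class SolventModel:
    """Solvent described as an ensemble of AIP types.

    ``theta`` is the total AIP density of the solvent (the dimensionless
    concentration-like parameter of the bound/solvated free-energy
    expressions); ``solvent_aips`` lists (epsilon, mole_fraction) pairs.
    """

    theta: float
    solvent_aips: list[tuple[float, float]]
    temperature: float = 298.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not self.solvent_aips:
            raise ValueError("solvent ensemble is empty")
        total = sum(x for _, x in self.solvent_aips)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"solvent mole fractions sum to {total}, not 1")


@dataclass
class ContactRecord:
    """One paired ligand-AIP / protein-AIP interaction.

    ``f_effective`` is the minimum of the two AIP fractions; ``ddG`` is the
    f-scaled free-energy contribution of the contact and ``decomposition``
    stores (dG_B(i), dG_B(j), dG_S(i), dG_S(j)).
    """

    ligand_aip: AIP
    protein_aip: AIP
    contact_type: str  # "hbond" | "nonpolar"
    distance: float
    f_effective: float
    ddG: float | None = None
    decomposition: tuple[float, float, float, float] | None = None


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_molecule(m: MoleculeGraph) -> list[str]:
    """Return a list of invariant violations (empty iff the graph is valid).

    Checks: unique atom ids, finite coordinates, bonds reference existing
    distinct atoms, the graph is connected, AIP fractions lie in {0.5, 1.0}
    consistently with their class, and AIP parents resolve.
    """
    violations: list[str] = []
    ids = [a.atom_id for a in m.atoms]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            violations.append(f"duplicate atom id {i!r}")
        seen.add(i)
    for a in m.atoms:
        if not np.all(np.isfinite(a.coords)) or a.coords.shape != (3,):
            violations.append(f"atom {a.atom_id!r} has non-finite or misshapen coords")
        if a.sybyl_type and not a.sybyl_type.split(".")[0].upper().startswith(a.element.upper()):
            violations.append(
                f"atom {a.atom_id!r}: sybyl type {a.sybyl_type!r} inconsistent with element {a.element!r}")
    for a, b, order in m.bonds:
        if a == b:
            violations.append(f"self-bond on atom {a!r}")
        for end in (a, b):
            if end not in seen:
                violations.append(f"bond ({a!r}, {b!r}) references missing atom id {end!r}")
        if order <= 0:
            violations.append(f"bond ({a!r}, {b!r}) has non-positive order {order}")
    if len(m.atoms) > 1:
        adj: dict[str, set[str]] = {i: set() for i in seen}
        for a, b, _ in m.bonds:
            if a in adj and b in adj:
                adj[a].add(b)
                adj[b].add(a)
        stack, reached = [ids[0]], {ids[0]}
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in reached:
                    reached.add(nb)
                    stack.append(nb)
        if reached != set(seen):
            missing = sorted(set(seen) - reached)
            violations.append(f"graph not connected; unreachable atoms {missing}")
    for k, p in enumerate(m.aips):
        if p.parent_atom_id not in seen:
            violations.append(f"AIP #{k} parent atom {p.parent_atom_id!r} does not exist")
        if p.fraction not in (0.5, 1.0):
            violations.append(f"AIP #{k} fraction {p.fraction} not in {{0.5, 1.0}}")
        else:
            is_pi = p.aip_class in PI_DENSITY_CLASSES
            if is_pi != (p.fraction == 0.5):
                violations.append(
                    f"AIP #{k} fraction {p.fraction} inconsistent with class {p.aip_class.value}")
        if not np.all(np.isfinite(p.position)) or not math.isfinite(p.epsilon):
            violations.append(f"AIP #{k} has non-finite position or epsilon")
    return violations


# ---------------------------------------------------------------------------
# CML serialization (with namespaced AIP extension)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.8f}"


def write_cml(m: MoleculeGraph, path=None) -> str:
    """Serialize a molecule (atoms, bonds, AIPs) to CML.

    AIPs are carried in an ``aip:aipArray`` extension element.  Returns the
    XML text; also writes it to ``path`` when given.
    """
    root = etree.Element(f"{{{CML_NS}}}molecule", nsmap=_NSMAP)
    arr = etree.SubElement(root, f"{{{CML_NS}}}atomArray")
    for a in m.atoms:
        el = etree.SubElement(arr, f"{{{CML_NS}}}atom")
        el.set("id", a.atom_id)
        el.set("elementType", a.element)
        el.set("x3", _fmt(a.coords[0]))
        el.set("y3", _fmt(a.coords[1]))
        el.set("z3", _fmt(a.coords[2]))
        if a.hybridization is not Hybridization.NONE:
            el.set(f"{{{AIP_NS}}}hybridization", a.hybridization.value)
        if a.sybyl_type:
            el.set(f"{{{AIP_NS}}}sybylType", a.sybyl_type)
    barr = etree.SubElement(root, f"{{{CML_NS}}}bondArray")
    for a, b, order in m.bonds:
        el = etree.SubElement(barr, f"{{{CML_NS}}}bond")
        el.set("atomRefs2", f"{a} {b}")
        el.set("order", repr(order))
    if m.aips:
        parr = etree.SubElement(root, f"{{{AIP_NS}}}aipArray")
        for p in m.aips:
            el = etree.SubElement(parr, f"{{{AIP_NS}}}aip")
            el.set("parentAtom", p.parent_atom_id)
            el.set("epsilon", _fmt(p.epsilon))
            el.set("fraction", repr(p.fraction))
            el.set("aipClass", p.aip_class.value)
            el.set("x3", _fmt(p.position[0]))
            el.set("y3", _fmt(p.position[1]))
            el.set("z3", _fmt(p.position[2]))
    text = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_cml(source) -> MoleculeGraph:
    """Parse CML produced by :func:`write_cml` (or compatible documents).

    ``source`` is a path or an XML string.  AIP extension elements are
    optional; when present each must carry epsilon and a resolvable parent
    atom.
    """
    if isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    else:
        root = etree.parse(str(source)).getroot()
    atoms: list[AtomSite] = []
    for el in root.findall(f"{{{CML_NS}}}atomArray/{{{CML_NS}}}atom"):
        atoms.append(AtomSite(
            atom_id=el.get("id"),
            element=el.get("elementType"),
            hybridization=Hybridization(el.get(f"{{{AIP_NS}}}hybridization", "none")),
            sybyl_type=el.get(f"{{{AIP_NS}}}sybylType", ""),
            coords=np.array([float(el.get(k)) for k in ("x3", "y3", "z3")]),
        ))
    bonds: list[tuple[str, str, float]] = []
    for el in root.findall(f"{{{CML_NS}}}bondArray/{{{CML_NS}}}bond"):
        a, b = el.get("atomRefs2").split()
        raw = el.get("order", "1")
        order = {"S": 1.0, "D": 2.0, "T": 3.0, "A": 1.5}.get(raw, None)
        bonds.append((a, b, float(raw) if order is None else order))
    aips: list[AIP] = []
    ids = {a.atom_id for a in atoms}
    for k, el in enumerate(root.findall(f"{{{AIP_NS}}}aipArray/{{{AIP_NS}}}aip")):
        eps = el.get("epsilon")
        parent = el.get("parentAtom")
        if eps is None:
            raise ValueError(f"AIP element #{k} is missing an epsilon attribute")
        if parent is None or parent not in ids:
            raise ValueError(f"AIP element #{k} has missing/unresolvable parent atom {parent!r}")
        aips.append(AIP(
            position=np.array([float(el.get(x)) for x in ("x3", "y3", "z3")]),
            epsilon=float(eps),
            fraction=float(el.get("fraction", "1.0")),
            aip_class=AipClass(el.get("aipClass", "other")),
            parent_atom_id=parent,
        ))
    return MoleculeGraph(atoms=atoms, bonds=bonds, aips=aips)


# ---------------------------------------------------------------------------
# PDB I/O
#
# Biopython's parser handles coordinates/residues but does not expose CONECT
# records, and the PDB format carries neither bond orders nor hybridization,
# so the graph chemistry is completed here: CONECT records are read when
# present, remaining bonds are perceived from covalent radii, and
# hybridization is perceived from connectivity (heavy-neighbour counts,
# planarity for aromatic rings).
# ---------------------------------------------------------------------------

def write_pdb(m: MoleculeGraph, path=None, *, hetatm: bool = False) -> str:
    """Write a molecule to PDB text with CONECT records for every bond.

    AIPs are not written here; see :func:`aipmap.fragment_matching.
    write_aip_pdb` for the pseudo-atom representation.
    """
    lines: list[str] = []
    serial = {}
    for i, a in enumerate(m.atoms, start=1):
        serial[a.atom_id] = i
        record = "HETATM" if hetatm else "ATOM  "
        name = a.atom_id[:4]
        res = (a.residue_name or "MOL")[:3]
        chain = (a.chain_id or "A")[:1]
        resseq = a.residue_index if a.residue_index is not None else 1
        x, y, z = a.coords
        lines.append(
            f"{record}{i:>5} {name:<4} {res:<3} {chain}{resseq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2}"
        )
    for a, b, _ in m.bonds:
        lines.append(f"CONECT{serial[a]:>5}{serial[b]:>5}")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_complex_pdb(protein: MoleculeGraph, ligand: MoleculeGraph,
                      path=None) -> str:
    """Write protein (ATOM) and ligand (HETATM) into one PDB file with
    consistent serial numbering and CONECT records for both molecules."""
    lines: list[str] = []
    serial: dict[tuple[int, str], int] = {}
    n = 0
    for mol_idx, (mol, record) in enumerate(((protein, "ATOM  "),
                                             (ligand, "HETATM"))):
        for a in mol.atoms:
            n += 1
            serial[(mol_idx, a.atom_id)] = n
            res = (a.residue_name or ("MOL" if mol_idx == 0 else "LIG"))[:3]
            chain = (a.chain_id or ("A" if mol_idx == 0 else "B"))[:1]
            resseq = a.residue_index if a.residue_index is not None else 1
            x, y, z = a.coords
            lines.append(
                f"{record}{n:>5} {a.atom_id[:4]:<4} {res:<3} {chain}{resseq:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2}")
    for mol_idx, mol in enumerate((protein, ligand)):
        for a, b, _ in mol.bonds:
            lines.append(f"CONECT{serial[(mol_idx, a)]:>5}{serial[(mol_idx, b)]:>5}")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _perceive_bonds(atoms: Sequence[AtomSite], slack: float = 0.45) -> list[tuple[str, str, float]]:
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            ra = COVALENT_RADII.get(a.element)
            rb = COVALENT_RADII.get(b.element)
            if ra is None or rb is None:
                continue
            if a.element == "H" and b.element == "H":
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            if 0.1 < d < ra + rb + slack:
                bonds.append((a.atom_id, b.atom_id, 1.0))
    return bonds


def _ring_atoms(adj: dict[str, list[str]], max_size: int = 6) -> set[frozenset]:
    """Minimal cycle collection (5/6-rings) by bounded DFS; small graphs only."""
    rings: set[frozenset] = set()
    nodes = sorted(adj)
    for start in nodes:
        stack = [(start, [start])]
        while stack:
            cur, path = stack.pop()
            for nb in adj[cur]:
                if nb == start and len(path) >= 3:
                    rings.add(frozenset(path))
                elif nb not in path and len(path) < max_size:
                    stack.append((nb, path + [nb]))
    return {r for r in rings if len(r) in (5, 6)}


def perceive_chemistry(m: MoleculeGraph) -> None:
    """Fill in hybridization (and a default sybyl type) from connectivity.

    Carbon: 4 neighbours -> sp3, 3 -> sp2, 2 -> sp; atoms in a planar 5/6
    ring of sp2-compatible atoms are flagged aromatic.  Nitrogen/oxygen/
    sulfur are classified by neighbour count analogously.  This is a
    pragmatic perception for structures lacking explicit orders.
    """
    adj: dict[str, list[str]] = {a.atom_id: [] for a in m.atoms}
    for a, b, _ in m.bonds:
        adj[a].append(b)
        adj[b].append(a)
    index = m._index()

    def degree(aid):
        return len(adj[aid])

    for a in m.atoms:
        n = degree(a.atom_id)
        if a.element == "H":
            a.hybridization = Hybridization.NONE
        elif a.element == "C":
            a.hybridization = {4: Hybridization.SP3, 3: Hybridization.SP2,
                               2: Hybridization.SP}.get(n, Hybridization.SP3)
        elif a.element == "N":
            a.hybridization = Hybridization.SP3 if n >= 4 else (
                Hybridization.SP2 if n == 3 else Hybridization.SP2)
        elif a.element == "O":
            a.hybridization = Hybridization.SP3 if n >= 2 else Hybridization.SP2
        elif a.element == "S":
            a.hybridization = Hybridization.SP3
        else:
            a.hybridization = Hybridization.NONE

    # aromatic flag: planar 5/6-rings whose heavy members are sp2-compatible
    heavy_adj = {aid: [b for b in nbs if index[b].element != "H"]
                 for aid, nbs in adj.items()}
    for ring in _ring_atoms(heavy_adj):
        members = [index[aid] for aid in ring]
        if any(m_.element not in ("C", "N", "O", "S") for m_ in members):
            continue
        if any(m_.element == "C" and degree(m_.atom_id) > 3 for m_ in members):
            continue
        coords = np.array([m_.coords for m_ in members])
        centred = coords - coords.mean(axis=0)
        _, s, _ = np.linalg.svd(centred)
        if s[-1] < 0.15:  # near-planar
            for m_ in members:
                m_.hybridization = Hybridization.AROMATIC

    for a in m.atoms:
        if not a.sybyl_type:
            a.sybyl_type = _default_sybyl(a, adj, index)


def _default_sybyl(a: AtomSite, adj, index) -> str:
    if a.element == "H":
        nb = adj[a.atom_id]
        parent = index[nb[0]] if nb else None
        if parent is not None and parent.element in ("N", "O", "S"):
            return f"H.{parent.element}"
        return "H.soft"
    suffix = {Hybridization.SP3: "3", Hybridization.SP2: "2",
              Hybridization.SP: "1", Hybridization.AROMATIC: "ar"}.get(
        a.hybridization, "3")
    return f"{a.element}.{suffix}"


def read_pdb(path, *, het_is_ligand: bool = True,
             perceive: bool = True) -> tuple[MoleculeGraph, MoleculeGraph | None]:
    """Read a (protein, ligand) pair from a PDB file.

    ATOM records form the protein graph and HETATM records (excluding
    waters) the ligand graph (``None`` when absent).  Bonds come from
    CONECT records when available, completed by covalent-radius perception;
    hybridization is perceived from connectivity.
    """
    from Bio.PDB import PDBParser  # established coordinate/residue reader

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    prot_atoms: list[AtomSite] = []
    lig_atoms: list[AtomSite] = []
    serial_to_id: dict[int, str] = {}
    for model in structure:
        for chain in model:
            for residue in chain:
                het = residue.id[0].strip()
                if het == "W" or residue.resname in ("HOH", "WAT"):
                    continue
                is_het = bool(het)
                for atom in residue:
                    aid = f"{chain.id}{residue.id[1]}.{atom.name}.{atom.serial_number}"
                    site = AtomSite(
                        atom_id=aid,
                        element=(atom.element or atom.name[0]).capitalize(),
                        coords=np.array(atom.coord, dtype=float),
                        residue_name=residue.resname,
                        residue_index=residue.id[1],
                        chain_id=chain.id,
                    )
                    serial_to_id[atom.serial_number] = aid
                    (lig_atoms if (is_het and het_is_ligand) else prot_atoms).append(site)
        break  # first model only

    conect: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("CONECT"):
                fields = [line[6:11], line[11:16], line[16:21], line[21:26], line[26:31]]
                serials = [int(f) for f in fields if f.strip()]
                if not serials:
                    continue
                a0 = serials[0]
                for b0 in serials[1:]:
                    if a0 in serial_to_id and b0 in serial_to_id:
                        key = tuple(sorted((serial_to_id[a0], serial_to_id[b0])))
                        conect.append((key[0], key[1], 1.0))
    conect = sorted(set(conect))

    def build(atoms: list[AtomSite]) -> MoleculeGraph:
        ids = {a.atom_id for a in atoms}
        bonds = [b for b in conect if b[0] in ids and b[1] in ids]
        if not bonds:
            bonds = _perceive_bonds(atoms)
        g = MoleculeGraph(atoms=atoms, bonds=bonds)
        if perceive:
            perceive_chemistry(g)
        return g

    protein = build(prot_atoms)
    ligand = build(lig_atoms) if lig_atoms else None
    return protein, ligand
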