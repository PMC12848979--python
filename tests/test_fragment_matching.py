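"""Virtual-site geometry, the modified subgraph matcher and the library cover."""

import itertools

import numpy as np
import pytest

from aipmap import (
    MoleculeGraph,
    build_macromolecule_aips,
    fit_virtual_site_weights,
    fragment_from_molecule,
    load_fragment_library,
    make_backbone_chain,
    match_fragment,
    place_virtual_site,
    write_fragment_library,
)
from aipmap.aip_core import Hybridization
from aipmap.fragment_matching import DegenerateAnchorError, select_anchor_atoms
from aipmap.fixtures import _benzene_graph, _methanol_graph, _nma_graph

from conftest import make_aip, make_atom, random_rotation


# ---------------------------------------------------------------------------
# Brute-force matching oracle: injective maps enumerated recursively under
# the same modified rules, written independently of the networkx path.
# ---------------------------------------------------------------------------

def _oracle_allowed(frag, tgt, f_id, t_id):
    fa, ta = frag.atom(f_id), tgt.atom(t_id)
    if fa.element == "H":
        if ta.element == "H":
            return True
        if ta.element != "C":
            return False
        if not any(frag.atom(nb).element == "C" for nb in frag.neighbors(f_id)):
            return False
        if ta.hybridization is Hybridization.SP3:
            return True
        return any(tgt.atom(nb).element == "C"
                   and tgt.atom(nb).hybridization is Hybridization.SP3
                   for nb in tgt.neighbors(t_id))
    if fa.element != ta.element:
        return False
    if fa.hybridization is Hybridization.NONE or ta.hybridization is Hybridization.NONE:
        return True
    return fa.hybridization == ta.hybridization


def brute_force_matches(frag: MoleculeGraph, tgt: MoleculeGraph,
                        assigned=frozenset()):
    """All injective maps preserving bonds under the modified rules."""
    f_ids = [a.atom_id for a in frag.atoms]
    # order fragment atoms so each (after the first) touches an earlier one
    order, placed = [], set()
    pending = list(f_ids)
    while pending:
        nxt = None
        for f in pending:
            if not placed or any(nb in placed for nb in frag.neighbors(f)):
                nxt = f
                break
        nxt = nxt or pending[0]
        order.append(nxt)
        placed.add(nxt)
        pending.remove(nxt)
    t_ids = [a.atom_id for a in tgt.atoms if a.atom_id not in assigned]
    t_adj = {t: set(tgt.neighbors(t)) & set(t_ids) for t in t_ids}
    results = []

    def rec(i, mapping, used):
        if i == len(order):
            results.append(dict(mapping))
            return
        f = order[i]
        f_nbs_mapped = [mapping[nb] for nb in frag.neighbors(f) if nb in mapping]
        if f_nbs_mapped:
            cands = set.intersection(*[t_adj[t] for t in f_nbs_mapped])
        else:
            cands = set(t_ids)
        for t in sorted(cands - used):
            if not _oracle_allowed(frag, tgt, f, t):
                continue
            mapping[f] = t
            rec(i + 1, mapping, used | {t})
            del mapping[f]

    rec(0, {}, set())
    return {tuple(sorted(m.items())) for m in results}


def _random_molecule(rng, n, elements=("C", "N", "O", "H")):
    atoms, bonds = [], []
    for i in range(n):
        el = "C" if i == 0 else str(rng.choice(elements))
        hyb = Hybridization.NONE if el == "H" else \
            Hybridization(str(rng.choice(["sp3", "sp2"])))
        atoms.append(make_atom(f"x{i}", el, rng.normal(size=3) * 2.0, hyb))
        if i > 0:
            j = int(rng.integers(0, i))
            if atoms[j].element == "H":  # keep H terminal
                j = 0
            bonds.append((f"x{j}", f"x{i}", 1.0))
    return MoleculeGraph(atoms=atoms, bonds=bonds)


class TestVirtualSiteGeometry:
    def test_aip_at_atom2_gives_unit_w12(self):
        anchors = [np.zeros(3), np.array([1.5, 0, 0]), np.array([0, 1.2, 0])]
        assert fit_virtual_site_weights(anchors, anchors[1]) == pytest.approx(
            (1.0, 0.0, 0.0), abs=1e-12)

    def test_cross_product_basis_vector(self):
        anchors = [np.zeros(3), np.array([1.5, 0, 0]), np.array([0, 1.2, 0])]
        target = anchors[0] + np.cross(anchors[1], anchors[2])
        assert fit_virtual_site_weights(anchors, target) == pytest.approx(
            (0.0, 0.0, 1.0), abs=1e-12)

    def test_zero_weights_place_at_atom1(self):
        anchors = [np.array([0.3, -1, 2.0]), np.array([1.5, 0, 0]),
                   np.array([0, 1.2, 0])]
        np.testing.assert_allclose(
            place_virtual_site(anchors, (0, 0, 0)), anchors[0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_fit_then_place_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        anchors = [rng.normal(size=3) * 2 for _ in range(3)]
        target = rng.normal(size=3) * 3
        w = fit_virtual_site_weights(anchors, target)
        np.testing.assert_allclose(place_virtual_site(anchors, w), target,
                                   atol=1e-8)

    def test_rigid_motion_equivariance(self):
        rng = np.random.default_rng(42)
        anchors = [rng.normal(size=3) for _ in range(3)]
        target = rng.normal(size=3)
        w = fit_virtual_site_weights(anchors, target)
        R, t = random_rotation(rng), rng.normal(size=3)
        moved = [R @ a + t for a in anchors]
        np.testing.assert_allclose(place_virtual_site(moved, w), R @ target + t,
                                   atol=1e-6)

    def test_collinear_anchors_raise_named_error(self):
        anchors = [np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0])]
        with pytest.raises(DegenerateAnchorError, match="frag7"):
            fit_virtual_site_weights(anchors, np.ones(3), context="frag7")

    def test_anchor_selection_prefers_fewest_bonds_then_element(self):
        # a1 closest to the AIP; candidates one bond away: C and O -> C wins
        atoms = [make_atom("a1", "N", (0, 0, 0)),
                 make_atom("c", "C", (1.4, 0.2, 0)),
                 make_atom("o", "O", (-1.2, 0.6, 0)),
                 make_atom("far", "C", (2.8, 0.4, 0.5))]
        bonds = [("a1", "c", 1.0), ("a1", "o", 1.0), ("c", "far", 1.0)]
        m = MoleculeGraph(atoms=atoms, bonds=bonds)
        assert select_anchor_atoms(m, (0, 0, 1.5)) == ("a1", "c", "o")


try:
    from hypothesis import assume, given, settings
    from hypothesis import strategies as st

    coord = st.floats(-8.0, 8.0, allow_nan=False, allow_infinity=False)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(coord, min_size=12, max_size=12))
    def test_fit_place_round_trip_property(vals):
        """Any non-degenerate anchor triple reconstructs any site exactly."""
        pts = np.array(vals).reshape(4, 3)
        anchors, target = list(pts[:3]), pts[3]
        cross = np.cross(anchors[1] - anchors[0], anchors[2] - anchors[0])
        assume(np.linalg.norm(cross) > 1e-3)
        w = fit_virtual_site_weights(anchors, target)
        np.testing.assert_allclose(place_virtual_site(anchors, w), target,
                                   atol=1e-7)
except ImportError:  # hypothesis is an optional test dependency
    pass


class TestMatchFragment:
    def test_fragment_identical_to_target_contains_identity(self):
        m = _methanol_graph()
        results = match_fragment(m, m)
        identity = {a.atom_id: a.atom_id for a in m.atoms}
        assert identity in [r.atom_map for r in results]

    def test_methane_does_not_match_benzene(self):
        c = make_atom("c", "C", (0, 0, 0), Hybridization.SP3)
        hs = [make_atom(f"h{k}", "H", p, Hybridization.NONE)
              for k, p in enumerate([(1.1, 0, 0), (-0.4, 1, 0),
                                     (-0.4, -0.5, 0.9), (-0.4, -0.5, -0.9)])]
        methane = MoleculeGraph(atoms=[c] + hs,
                                bonds=[("c", f"h{k}", 1.0) for k in range(4)])
        assert match_fragment(methane, _benzene_graph()) == []

    def test_nma_matches_dipeptide_backbone(self):
        """The amide fragment embeds in a capped diamide; truncation
        hydrogens take over backbone carbons."""
        chain = make_backbone_chain(1)
        results = match_fragment(_nma_graph(), chain)
        assert results
        amide_cover = {"C0", "O0", "N0", "HN0"}
        assert any(amide_cover <= set(r.atom_map.values()) for r in results)
        assert any(r.h_to_c_matches for r in results)

    def test_assigned_atoms_are_excluded(self):
        m = _methanol_graph()
        assert match_fragment(m, m, assigned_atoms={"O1"}) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        tgt = _random_molecule(rng, int(rng.integers(5, 12)))
        frag = _random_molecule(rng, int(rng.integers(2, 6)))
        got = {tuple(sorted(r.atom_map.items())) for r in match_fragment(frag, tgt)}
        assert got == brute_force_matches(frag, tgt)

    def test_agrees_with_brute_force_on_nma_dipeptide(self):
        chain = make_backbone_chain(1)
        nma = _nma_graph()
        got = {tuple(sorted(r.atom_map.items())) for r in match_fragment(nma, chain)}
        assert got == brute_force_matches(nma, chain)
        assert got  # non-empty


class TestBuildMacromolecule:
    def test_target_identical_to_fragment_reproduces_aips(self, library):
        frag = library[0]
        target = frag.graph.copy()
        target.aips = []
        decorated, uncovered = build_macromolecule_aips(target, [frag])
        assert uncovered == []
        assert len(decorated.aips) == len(frag.graph.aips)
        got = sorted(decorated.aips, key=lambda p: tuple(p.position))
        want = sorted(frag.graph.aips, key=lambda p: tuple(p.position))
        for g, w in zip(got, want):
            np.testing.assert_allclose(g.position, w.position, atol=1e-6)
            assert g.epsilon == w.epsilon

    def test_backbone_polar_atoms_covered_alpha_carbons_bare(self, library):
        chain = make_backbone_chain(2)
        decorated, uncovered = build_macromolecule_aips(chain, library)
        parents = {p.parent_atom_id for p in decorated.aips}
        for a in chain.atoms:
            if a.element in ("O", "N") or a.atom_id.startswith("HN"):
                assert a.atom_id in parents, a.atom_id
            if a.atom_id.startswith("CA"):
                assert a.atom_id not in parents
        assert uncovered == []

    def test_overlapping_fragments_largest_first_no_double_aips(self, library):
        # ethanol and methanol overlap on any alcohol group; ethanol (larger)
        # must claim it and no atom may hold AIPs from two fragments
        eth = next(f for f in library if f.fragment_id == "ethanol")
        target = eth.graph.copy()
        target.aips = []
        decorated, _ = build_macromolecule_aips(target, library)
        per_parent = {}
        for p in decorated.aips:
            per_parent.setdefault(p.parent_atom_id, set()).add(p.epsilon)
        # the ethanol O epsilon (-5.1), not the methanol O epsilon (-5.5)
        assert per_parent["O1"] == {-5.1}

    def test_rigid_motion_equivariance(self, library):
        chain = make_backbone_chain(1)
        d1, _ = build_macromolecule_aips(chain, library)
        rng = np.random.default_rng(5)
        R, t = random_rotation(rng), rng.normal(size=3) * 10
        moved = chain.copy()
        for a in moved.atoms:
            a.coords = R @ a.coords + t
        d2, _ = build_macromolecule_aips(moved, library)
        assert len(d1.aips) == len(d2.aips)
        for p, q in zip(d1.aips, d2.aips):
            assert p.parent_atom_id == q.parent_atom_id and p.epsilon == q.epsilon
            np.testing.assert_allclose(R @ p.position + t, q.position, atol=1e-6)

    def test_deterministic_under_atom_input_order(self, library):
        chain = make_backbone_chain(1)
        shuffled = chain.copy()
        rng = np.random.default_rng(3)
        rng.shuffle(shuffled.atoms)
        d1, _ = build_macromolecule_aips(chain, library)
        d2, _ = build_macromolecule_aips(shuffled, library)
        k1 = sorted((p.parent_atom_id, round(p.epsilon, 6),
                     tuple(np.round(p.position, 6))) for p in d1.aips)
        k2 = sorted((p.parent_atom_id, round(p.epsilon, 6),
                     tuple(np.round(p.position, 6))) for p in d2.aips)
        assert k1 == k2

    def test_coverage_monotone_in_library(self, library):
        chain = make_backbone_chain(2)
        full, _ = build_macromolecule_aips(chain, library)
        n_full = len({p.parent_atom_id for p in full.aips})
        for drop in range(len(library)):
            reduced = [f for k, f in enumerate(library) if k != drop]
            part, _ = build_macromolecule_aips(chain, reduced)
            assert len({p.parent_atom_id for p in part.aips}) <= n_full


class TestLibraryIO:
    def test_round_trip(self, library, tmp_path):
        path = tmp_path / "lib.xml"
        write_fragment_library(library, path)
        back = load_fragment_library(path)
        assert [f.fragment_id for f in back] == [f.fragment_id for f in library]
        for a, b in zip(back, library):
            assert a.n_atoms == b.n_atoms
            assert len(a.aip_templates) == len(b.aip_templates)
            for ta, tb in zip(a.aip_templates, b.aip_templates):
                assert ta.anchor_atoms == tb.anchor_atoms
                np.testing.assert_allclose(ta.weights, tb.weights, atol=1e-9)

    def test_weights_reconstruct_own_geometry(self, library):
        for frag in library:
            for tmpl, aip in zip(frag.aip_templates, frag.graph.aips):
                coords = [frag.graph.atom(a).coords for a in tmpl.anchor_atoms]
                from aipmap import place_virtual_site

                np.testing.assert_allclose(place_virtual_site(coords, tmpl.weights),
                                           aip.position, atol=1e-8)

    def test_malformed_entry_names_fragment(self, tmp_path):
        bad = """<AipForceField><Fragment name="broken">
            <Atom id="a1" element="C" x="0" y="0" z="0"/>
            <Atom id="a2" element="O" x="1.4" y="0" z="0"/>
            <Aip class="lone_pair" epsilon="nope" fraction="1.0" parent="a2"
                 atom1="a2" atom2="a1" atom3="a1" w12="0" w13="0" wcross="0"/>
            </Fragment></AipForceField>"""
        path = tmp_path / "bad.xml"
        path.write_text(bad)
        with pytest.raises(ValueError, match="broken"):
            load_fragment_library(path)

    def test_shipped_synthetic_library_loads(self):
        from importlib import resources

        ref = resources.files("aipmap.data").joinpath("protein_aip_ff_synthetic.xml")
        lib = load_fragment_library(str(ref))
        names = {f.fragment_id for f in lib}
        assert {"n-methylacetamide", "methanol", "dimethyl-sulfide",
                "benzene"} <= names
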