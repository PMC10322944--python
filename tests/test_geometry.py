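"""Plane fitting, inter-ring angles, superposition and contacts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pbsdyn.errors import DegenerateGeometryError, RingResolutionError, SelectionError
from pbsdyn.geometry import (
    RingPlane,
    bilin_conformation,
    contact_map,
    fit_plane,
    inter_ring_angle,
    rank_red_candidates,
    superpose,
)
from pbsdyn.simulate import TetrapyrroleSpec, make_tetrapyrrole
from pbsdyn.structure import Atom, BilinInstance, Chain, Residue, StructureModel

RNG = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# fit_plane
# ---------------------------------------------------------------------------


def test_fit_plane_flat_pentagon():
    pts = np.array(
        [[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 5, endpoint=False)]
    )
    plane = fit_plane(pts)
    assert abs(abs(plane.normal[2]) - 1.0) < 1e-12
    assert plane.planarity_rms < 1e-12


@pytest.mark.parametrize(
    "points",
    [
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),                      # 2 points
        np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [2.0, 2.0, 2.0]]),    # collinear
    ],
)
def test_fit_plane_degenerate(points):
    with pytest.raises(DegenerateGeometryError):
        fit_plane(points)


def _grid_search_normal(points, step_deg=1.0):
    """Brute-force plane fit: scan unit-sphere normals on a 1-degree grid."""
    centered = points - points.mean(axis=0)
    best, best_cost = None, np.inf
    thetas = np.radians(np.arange(0.0, 180.0, step_deg))
    phis = np.radians(np.arange(0.0, 360.0, step_deg))
    for th in thetas:
        st, ct = np.sin(th), np.cos(th)
        normals = np.column_stack(
            [st * np.cos(phis), st * np.sin(phis), np.full_like(phis, ct)]
        )
        costs = np.sum((centered @ normals.T) ** 2, axis=0)
        i = int(np.argmin(costs))
        if costs[i] < best_cost:
            best_cost, best = costs[i], normals[i]
    return best


def test_fit_plane_matches_grid_search_oracle():
    """SVD plane normal agrees with an exhaustive unit-sphere search."""
    pts = np.array(
        [[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 5, endpoint=False)]
    )
    pts += RNG.normal(0, 0.05, pts.shape)
    R = Rotation.random(random_state=3).as_matrix()
    pts = pts @ R.T + np.array([4.0, -2.0, 7.0])
    fitted = fit_plane(pts).normal
    oracle = _grid_search_normal(pts)
    ang = np.degrees(np.arccos(np.clip(abs(fitted @ oracle), -1, 1)))
    assert ang < 2.0


# ---------------------------------------------------------------------------
# inter_ring_angle
# ---------------------------------------------------------------------------


def _plane(normal):
    n = np.asarray(normal, float)
    return RingPlane(np.zeros(3), n / np.linalg.norm(n), 0.0)


@pytest.mark.parametrize(
    "n1, n2, expected",
    [
        ((0, 0, 1), (0, 0, 1), 0.0),      # identical planes
        ((0, 0, 1), (1, 0, 0), 90.0),     # orthogonal
        ((0, 0, 1), (0, 0, -1), 0.0),     # antiparallel: absolute convention
    ],
)
def test_inter_ring_angle_cases(n1, n2, expected):
    assert inter_ring_angle(_plane(n1), _plane(n2)) == pytest.approx(expected, abs=1e-10)


def test_inter_ring_angle_symmetry_and_flip():
    for _ in range(20):
        p, q = _plane(RNG.normal(size=3)), _plane(RNG.normal(size=3))
        a = inter_ring_angle(p, q)
        assert 0.0 <= a <= 90.0
        assert inter_ring_angle(q, p) == pytest.approx(a, abs=1e-12)
        flipped = RingPlane(q.centroid, -q.normal, q.planarity_rms)
        assert inter_ring_angle(p, flipped) == pytest.approx(a, abs=1e-12)


def test_angles_rigid_motion_invariant():
    """Rotating+translating a bilin leaves the inter-ring angles unchanged."""
    bilin = make_tetrapyrrole(TetrapyrroleSpec(26.0, 7.0, 8.0))
    base = bilin_conformation(bilin).angles
    for seed in range(5):
        R = Rotation.random(random_state=seed).as_matrix()
        t = RNG.normal(0, 20, 3)
        moved = BilinInstance(
            label=bilin.label,
            host_chain_id=bilin.host_chain_id,
            atoms=[
                Atom(a.name, a.element, R @ a.position + t, a.residue_name,
                     a.residue_number, a.chain_id, a.is_hydrogen)
                for a in bilin.atoms
            ],
        )
        np.testing.assert_allclose(bilin_conformation(moved).angles, base, atol=1e-9)


# ---------------------------------------------------------------------------
# bilin_conformation
# ---------------------------------------------------------------------------


def test_planar_tetrapyrrole_is_flat(flat_bilin):
    conf = bilin_conformation(flat_bilin)
    assert conf.angles == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)
    assert conf.planarity_score == pytest.approx(0.0, abs=1e-9)


def test_prescribed_angles_recovered():
    conf = bilin_conformation(make_tetrapyrrole(TetrapyrroleSpec(26.0, 7.0, 8.0)))
    np.testing.assert_allclose(conf.angles, (26.0, 7.0, 8.0), atol=1e-6)


def test_missing_ring_atoms_reported(flat_bilin):
    broken = BilinInstance(
        label="broken",
        host_chain_id="X",
        atoms=[a for a in flat_bilin.atoms if a.name != "C2C"],
    )
    with pytest.raises(RingResolutionError, match="C2C"):
        bilin_conformation(broken)


# ---------------------------------------------------------------------------
# superpose
# ---------------------------------------------------------------------------


def test_superpose_identity():
    pts = RNG.normal(0, 5, (10, 3))
    res = superpose(pts, pts)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
    assert res.rmsd_fit == pytest.approx(0.0, abs=1e-9)


def test_superpose_recovers_random_rotation():
    pts = RNG.normal(0, 5, (12, 3))
    for seed in range(10):
        R = Rotation.random(random_state=seed).as_matrix()
        t = RNG.normal(0, 10, 3)
        moved = pts @ R.T + t
        res = superpose(pts, moved)
        assert res.rmsd_fit < 1e-9
        np.testing.assert_allclose(res.rotation @ R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.transform(moved), pts, atol=1e-9)


def test_superpose_beats_random_transforms():
    """Optimality: no random rigid transform yields a lower fit RMSD."""
    ref = RNG.normal(0, 5, (15, 3))
    mob = ref + RNG.normal(0, 0.5, ref.shape)
    best = superpose(ref, mob).rmsd_fit
    for seed in range(100):
        R = Rotation.random(random_state=seed).as_matrix()
        t = RNG.normal(0, 1, 3)
        rmsd = np.sqrt(np.mean(np.sum((ref - (mob @ R.T + t)) ** 2, axis=1)))
        assert best <= rmsd + 1e-12


def test_superpose_target_not_refit():
    """The target RMSD uses the fit transform; a shifted target keeps it."""
    ref = RNG.normal(0, 5, (10, 3))
    R = Rotation.random(random_state=1).as_matrix()
    mob = ref @ R.T
    offset = np.array([1.0, 0.0, 0.0])
    tgt_ref = RNG.normal(0, 5, (4, 3))
    tgt_mob = (tgt_ref + offset) @ R.T
    res = superpose(ref, mob, target_pairs=(tgt_ref, tgt_mob))
    assert res.rmsd_fit < 1e-9
    assert res.rmsd_target == pytest.approx(1.0, abs=1e-9)


def test_superpose_selection_errors():
    pts = RNG.normal(0, 1, (5, 3))
    with pytest.raises(SelectionError):
        superpose(pts, pts[:4])
    with pytest.raises(DegenerateGeometryError):
        superpose(pts[:2], pts[:2])


# ---------------------------------------------------------------------------
# contact_map
# ---------------------------------------------------------------------------


def _atom(name, pos, chain="P", resname="GLY", resnum=1, element="C"):
    return Atom(name, element, np.asarray(pos, float), resname, resnum, chain)


def _model_with(bilin, extra_atoms):
    residues = {}
    for a in extra_atoms:
        residues.setdefault((a.chain_id, a.residue_number, a.residue_name), []).append(a)
    chains = {}
    for (cid, num, name), atoms in residues.items():
        chains.setdefault(cid, []).append(Residue(name=name, number=num, atoms=atoms))
    chain_objs = [Chain(chain_id=cid, residues=res, is_polymer=False) for cid, res in chains.items()]
    chain_objs.append(
        Chain(
            chain_id=bilin.chain_id,
            residues=[Residue(bilin.residue_name, bilin.residue_number, list(bilin.atoms))],
        )
    )
    return StructureModel("contact-test", chain_objs)


def test_contact_at_exact_cutoff_included(flat_bilin):
    anchor = flat_bilin.atoms[0].position
    partner = _atom("CB", anchor + np.array([0.0, 0.0, 4.0]))
    model = _model_with(flat_bilin, [partner])
    recs = contact_map(flat_bilin, model, cutoff=4.0)
    assert any(r.partner_atom == "CB" and r.distance == pytest.approx(4.0) for r in recs)


def test_contact_empty_model(flat_bilin):
    model = _model_with(flat_bilin, [])
    assert contact_map(flat_bilin, model, cutoff=4.0) == []


def test_contacts_sorted_and_monotone_in_cutoff(toy_rod):
    model, _ = toy_rod
    from pbsdyn.structure import extract_bilins

    bilin = extract_bilins(model)[0]
    counts = []
    for cutoff in (2.0, 4.0, 6.0, 10.0):
        recs = contact_map(bilin, model, cutoff=cutoff)
        assert all(r.distance <= cutoff for r in recs)
        d = [r.distance for r in recs]
        assert d == sorted(d)
        counts.append(len(recs))
    assert counts == sorted(counts)


def test_hydrogens_excluded(flat_bilin):
    anchor = flat_bilin.atoms[0].position
    h = Atom("H1", "H", anchor + np.array([0.0, 0.0, 1.0]), "GLY", 1, "P", is_hydrogen=True)
    model = _model_with(flat_bilin, [h])
    assert contact_map(flat_bilin, model, cutoff=4.0) == []
    assert len(contact_map(flat_bilin, model, cutoff=4.0, exclude_hydrogens=False)) > 0


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def _conf(label, a, b, c):
    from pbsdyn.geometry import BilinConformation

    return BilinConformation(label, a, b, c)


def test_ranking_dominance():
    report = rank_red_candidates([_conf("x", 26, 7, 8), _conf("y", 28, 9, 38)])
    assert report.top_candidate.bilin_label == "x"


def test_ranking_all_equal_reports_tie():
    confs = [_conf(l, 20, 10, 10) for l in "abc"]
    with pytest.warns(UserWarning, match="tied"):
        report = rank_red_candidates(confs)
    assert report.ties == (("a", "b", "c"),)


def test_toy_rod_red_candidate(toy_rod):
    model, _ = toy_rod
    from pbsdyn.structure import assign_bilin_labels, extract_bilins

    bilins = assign_bilin_labels(extract_bilins(model), model, {"CpcL": "L"})
    confs = [bilin_conformation(b) for b in bilins]
    contacts = {b.label: contact_map(b, model) for b in bilins}
    report = rank_red_candidates(confs, contacts, ["L"])
    assert report.top_candidate.bilin_label == "1I-b82-2"
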