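"""Kabsch superposition and displacement profiling.

The independent oracle for the rigid fit is a brute-force scan over rotations
parametrized by three Euler angles on a coarse grid, followed by local
refinement — it never calls the implementation under test.
"""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from quatlock import displacement_profile, kabsch_fit, max_displacement
from quatlock.structure_io import RegionDefinition
from quatlock.superpose import RigidTransform
from quatlock.synthetic_data import make_apo_holo_pair, make_subunit
from quatlock.structure_io import Assembly


def _rmsd_for_rotation(angles, ref, mov):
    R = Rotation.from_euler("zyx", angles).as_matrix()
    moved = (mov - mov.mean(axis=0)) @ R.T
    target = ref - ref.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))


def brute_force_min_rmsd(ref, mov, n_grid=12):
    """Euler-grid scan with local refinement; independent of the Kabsch path."""
    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    best = (None, np.inf)
    for a in grid:
        for b in np.linspace(-np.pi / 2, np.pi / 2, n_grid // 2):
            for c in grid:
                r = _rmsd_for_rotation((a, b, c), ref, mov)
                if r < best[1]:
                    best = ((a, b, c), r)
    res = minimize(_rmsd_for_rotation, best[0], args=(ref, mov), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return float(res.fun)


def test_identical_sets_rmsd_zero():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    fit = kabsch_fit(pts, pts)
    assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(fit.transform.rotation, np.eye(3), atol=1e-10)
    assert fit.n_atoms_fit == 10


def test_exact_recovery_of_planted_transform():
    rng = np.random.default_rng(3)
    ref = rng.normal(size=(12, 3))
    Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    mov = ref @ Rz.T + np.array([1.0, 2.0, 3.0])
    fit = kabsch_fit(ref, mov)
    assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
    # recovered transform inverts the construction
    assert np.allclose(fit.transform.rotation, Rz.T, atol=1e-9)
    assert np.allclose(fit.transform.apply(mov), ref, atol=1e-9)


@pytest.mark.parametrize("seed", [7, 42, 99])
def test_kabsch_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    ref = rng.normal(scale=3.0, size=(6, 3))
    mov = rng.normal(scale=3.0, size=(6, 3))
    fit = kabsch_fit(ref, mov)
    oracle = brute_force_min_rmsd(ref, mov)
    assert fit.rmsd == pytest.approx(oracle, abs=1e-6)
    assert fit.rmsd <= oracle + 1e-9  # never worse than the scan


def test_too_few_points_errors():
    pts = np.zeros((2, 3))
    with pytest.raises(ValueError):
        kabsch_fit(pts, pts)


def test_collinear_sets_flagged_but_fit():
    line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
    fit = kabsch_fit(line, line + [0.0, 2.0, 0.0])
    assert fit.degenerate
    assert fit.rmsd == pytest.approx(0.0, abs=1e-9)


def test_rmsd_invariant_under_rigid_premotion():
    rng = np.random.default_rng(11)
    ref = rng.normal(size=(20, 3))
    mov = ref + rng.normal(scale=0.5, size=(20, 3))
    base = kabsch_fit(ref, mov).rmsd
    R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    moved = mov @ R.T + np.array([5.0, -3.0, 9.0])
    assert kabsch_fit(ref, moved).rmsd == pytest.approx(base, abs=1e-9)


def test_rmsd_symmetric():
    rng = np.random.default_rng(5)
    a = rng.normal(size=(15, 3))
    b = a + rng.normal(scale=0.3, size=(15, 3))
    assert kabsch_fit(a, b).rmsd == pytest.approx(kabsch_fit(b, a).rmsd, abs=1e-9)


def test_angle_axis_extraction():
    for angle in (0.0, 45.0, 90.0, 179.5, 180.0):
        R = Rotation.from_rotvec(np.radians(angle) * np.array([0, 0, 1.0])).as_matrix()
        t = RigidTransform(R, np.zeros(3))
        got_angle, axis = t.angle_axis()
        assert got_angle == pytest.approx(angle, abs=1e-6)
        if angle > 0:
            assert abs(axis @ [0, 0, 1.0]) == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# Displacement profiles


def _single_chain_assembly():
    chain = make_subunit(seed=4, n_residues=30)
    return Assembly(id="mono", chains=[chain])


def test_identical_chains_zero_displacement(mobile_region, stable_region):
    asm = _single_chain_assembly()
    chain = asm.chains[0]
    profile = displacement_profile(chain, chain, stable_region, mobile_region)
    for entry in profile:
        assert entry.ca_displacement == pytest.approx(0.0, abs=1e-12)
        assert entry.max_sidechain_displacement == pytest.approx(0.0, abs=1e-12)


def test_hinge_rotation_matches_chord_formula(mobile_region, stable_region):
    asm = _single_chain_assembly()
    hinge = asm.chains[0].residue(19).ca.coords
    apo, holo, truth = make_apo_holo_pair(
        asm, mobile_region, hinge, np.array([0.0, 0.0, 1.0]), angle=10.0
    )
    profile = displacement_profile(
        holo.chains[0], apo.chains[0], stable_region, mobile_region
    )
    assert profile.fit.rmsd == pytest.approx(0.0, abs=1e-9)
    measured = dict(profile.values("ca"))
    for seq, expected in truth.expected_ca.items():
        assert measured[seq] == pytest.approx(expected, abs=1e-6)
    mx, _ = max_displacement(profile, "ca")
    assert mx == pytest.approx(truth.expected_max_ca, abs=1e-6)


def test_displacement_monotone_in_hinge_angle(mobile_region, stable_region):
    asm = _single_chain_assembly()
    hinge = asm.chains[0].residue(19).ca.coords
    maxima = []
    for angle in (2.0, 5.0, 10.0, 20.0):
        apo, holo, _ = make_apo_holo_pair(
            asm, mobile_region, hinge, np.array([0.0, 0.0, 1.0]), angle=angle
        )
        profile = displacement_profile(
            holo.chains[0], apo.chains[0], stable_region, mobile_region
        )
        maxima.append(max_displacement(profile, "ca")[0])
    assert all(b > a for a, b in zip(maxima, maxima[1:]))


def test_missing_residues_excluded_and_listed(mobile_region, stable_region):
    asm = _single_chain_assembly()
    hinge = asm.chains[0].residue(19).ca.coords
    apo, holo, _ = make_apo_holo_pair(
        asm, mobile_region, hinge, np.array([0.0, 0.0, 1.0]), angle=5.0
    )
    apo.chains[0].residues = [r for r in apo.chains[0].residues if r.seq_num != 22]
    profile = displacement_profile(
        holo.chains[0], apo.chains[0], stable_region, mobile_region
    )
    assert 22 in profile.skipped_residues
    assert 22 not in {e.seq_num for e in profile}


def test_disjoint_report_region_warns_empty(stable_region):
    asm = _single_chain_assembly()
    far = RegionDefinition("far", ((200, 210),))
    with pytest.warns(UserWarning):
        profile = displacement_profile(asm.chains[0], asm.chains[0], stable_region, far)
    assert len(profile) == 0
    with pytest.raises(ValueError):
        max_displacement(profile, "ca")


def test_max_displacement_reports_argmax():
    from quatlock.superpose import DisplacementProfile, ResidueDisplacement

    profile = DisplacementProfile(
        entries=[
            ResidueDisplacement(1, "ALA", 1.0, 0.5),
            ResidueDisplacement(2, "ALA", 2.5, None),
            ResidueDisplacement(3, "GLY", 0.3, None),
        ]
    )
    val, seq = max_displacement(profile, "ca")
    assert (val, seq) == (2.5, 2)
    val, seq = max_displacement(profile, "sidechain")
    assert (val, seq) == (0.5, 1)
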