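"""Model Hamiltonian: geometry, softcore pair terms, energies, derivatives."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import torsionfep.model_system as ms
from torsionfep.model_system import (RFParams, SoftcoreParams, TorsionState,
                                     build_toy_mutation, dU_dlambda,
                                     measure_torsions, place_beads,
                                     potential_energy, softcore_lj,
                                     softcore_rf, topology_from_yaml,
                                     topology_to_yaml, wrap_deg)

from conftest import retabled

KT = ms.KB * 298.0


# ---------------------------------------------------------------------------
# reference (pure-python) energy, independent of the numba kernels
# ---------------------------------------------------------------------------

def reference_energy(top, state, lam, sc, variant="standard"):
    """Direct pair-sum over the topology using the scalar pair terms."""
    coords = place_beads(top, TorsionState(state))
    u_t = sum(k * (1.0 + math.cos(m * math.radians(state[d]) -
                                  math.radians(delta)))
              for d, k, m, delta in top.torsion_terms)
    u_nb = 0.0
    for i in range(top.n_beads):
        for j in range(i + 1, top.n_beads):
            if (i, j) in top.exclusions:
                continue
            if variant == "extra_exclusions" and (i, j) in top.extra_exclusions:
                continue
            bi, bj = top.beads[i], top.beads[j]
            r = float(np.linalg.norm(coords[i] - coords[j]))
            c12A = math.sqrt(bi.lj_A[0] * bj.lj_A[0])
            c6A = math.sqrt(bi.lj_A[1] * bj.lj_A[1])
            c12B = math.sqrt(bi.lj_B[0] * bj.lj_B[0])
            c6B = math.sqrt(bi.lj_B[1] * bj.lj_B[1])
            pert = (bi.is_perturbed or bj.is_perturbed)
            if not pert:
                u_nb += softcore_lj(r, c12A, c6A, c12A, c6A, 0.0, sc)
                u_nb += softcore_rf(r, bi.charge_A, bj.charge_A, 0.0, sc,
                                    top.rf)
            elif variant == "reference_R":
                d = sc.alpha_vdw * (c12A / c6A if c6A else 0.0) + r ** 6
                u_nb += (c12A / d - c6A) / d
            else:
                u_nb += softcore_lj(r, c12A, c6A, c12B, c6B, lam, sc)
                u_nb += softcore_rf(r, bi.charge_A, bj.charge_A, lam, sc,
                                    top.rf, bi.charge_B, bj.charge_B)
    return u_t + u_nb


# ---------------------------------------------------------------------------
# pair potentials
# ---------------------------------------------------------------------------

@settings(max_examples=300, deadline=None, derandomize=True)
@given(r=st.floats(0.01, 2.0),
       c12A=st.floats(1e-7, 1e-4), c6A=st.floats(1e-4, 2e-2),
       c12B=st.floats(0.0, 1e-4), c6B=st.floats(0.0, 2e-2),
       lam=st.floats(0.0, 1.0))
def test_softcore_lj_properties(r, c12A, c6A, c12B, c6B, lam):
    """Endpoint equivalence and finiteness hold for arbitrary pairs."""
    scp = SoftcoreParams(alpha_vdw=0.5)
    u = softcore_lj(r, c12A, c6A, c12B, c6B, lam, scp)
    assert math.isfinite(u)
    if lam == 0.0:
        plain = c12A / r ** 12 - c6A / r ** 6
        assert u == pytest.approx(plain, rel=1e-12, abs=1e-12)
    if lam == 1.0:
        plain = c12B / r ** 12 - c6B / r ** 6 if (c12B or c6B) else 0.0
        assert u == pytest.approx(plain, rel=1e-12, abs=1e-12)


@pytest.mark.parametrize("r", [0.25, 0.3, 0.45])
def test_softcore_lj_endpoints_reduce_to_plain(r, sc):
    """At lambda 0/1 the softcore LJ equals the plain end-state LJ."""
    c12A, c6A, c12B, c6B = 2.7e-5, 9.6e-3, 5.0e-6, 2.3e-3
    plain_A = c12A / r ** 12 - c6A / r ** 6
    plain_B = c12B / r ** 12 - c6B / r ** 6
    assert softcore_lj(r, c12A, c6A, c12B, c6B, 0.0, sc) == pytest.approx(
        plain_A, rel=1e-12)
    assert softcore_lj(r, c12A, c6A, c12B, c6B, 1.0, sc) == pytest.approx(
        plain_B, rel=1e-12)
    # dummy end state: fully decoupled
    assert softcore_lj(r, c12A, c6A, 0.0, 0.0, 1.0, sc) == 0.0


def test_softcore_lj_finite_at_contact(sc):
    """The vanishing state's softened branch stays finite as r -> 0."""
    u = softcore_lj(1e-9, 2.7e-5, 9.6e-3, 0.0, 0.0, 0.5,
                    SoftcoreParams(alpha_vdw=0.5))
    # direct evaluation of the Beutler-style branch at r = 0
    c126 = 2.7e-5 / 9.6e-3
    d = 0.5 * 0.25 * c126
    expected = 0.5 * (2.7e-5 / d - 9.6e-3) / d
    assert math.isfinite(u)
    assert u == pytest.approx(expected, rel=1e-6)


def test_softcore_lj_continuity_in_lambda(sc):
    lams = np.linspace(0, 1, 201)
    u = [softcore_lj(0.28, 2.7e-5, 9.6e-3, 0.0, 0.0, l, sc) for l in lams]
    assert np.all(np.isfinite(u))
    assert np.max(np.abs(np.diff(u))) < 0.1 * (np.max(u) - np.min(u) + 1e-12)


def test_softcore_lj_rejects_bad_input(sc):
    with pytest.raises(ValueError):
        softcore_lj(-0.1, 1e-5, 1e-3, 0, 0, 0.5, sc)
    with pytest.raises(ValueError):
        softcore_lj(0.3, 1e-5, 1e-3, 0, 0, 1.5, sc)


def test_softcore_rf_basics(sc):
    rf = RFParams()
    # neutral bead: zero at any distance/coupling
    assert softcore_rf(0.3, 0.0, 0.4, 0.5, sc, rf) == 0.0
    # endpoint identity: plain Coulomb + reaction field
    q1, q2, r = 0.38, -0.28, 0.31
    crf = rf.crf
    plain = ms.FELEC * q1 * q2 * (1 / r - 0.5 * crf * r ** 2 / rf.cutoff ** 3
                                  - (1 - 0.5 * crf) / rf.cutoff)
    assert softcore_rf(r, q1, q2, 0.0, sc, rf) == pytest.approx(plain,
                                                                rel=1e-12)
    # charge-swap symmetry
    assert softcore_rf(r, q1, q2, 0.37, sc, rf) == pytest.approx(
        softcore_rf(r, q2, q1, 0.37, sc, rf), rel=1e-14)


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

def test_default_topology_structure(top):
    assert top.n_dof == 2
    assert [lab for _, lab in top.torsion_dofs] == ["phi2", "psi2"]
    perturbed = [b for b in top.beads if b.is_perturbed]
    assert len(perturbed) == 1
    cb = perturbed[0]
    assert cb.lj_B == (0.0, 0.0) and cb.charge_B == 0.0   # dummy end state
    assert cb.charge_A == 0.0                              # neutral CH3
    # the four 1,4 partners exist and are not excluded
    assert len(top.extra_exclusions) == 4
    assert not (top.extra_exclusions & top.exclusions)
    # torsional terms produce barriers of ~1 kJ/mol only
    for _, k, _, _ in top.torsion_terms:
        assert 2.0 * k <= 1.0 + 1e-12


def test_exclusions_cover_12_and_13(top):
    bonds = set(top.bond_lengths)
    assert bonds <= top.exclusions
    neigh = {}
    for i, j in bonds:
        neigh.setdefault(i, set()).add(j)
        neigh.setdefault(j, set()).add(i)
    for c, ns in neigh.items():
        for i in ns:
            for j in ns:
                if i < j:
                    assert (i, j) in top.exclusions


def test_side_chain_variant_differs_only_in_cb():
    default = build_toy_mutation()
    ch2 = build_toy_mutation(side_chain_lj=(3.4e-5, 7.5e-3))
    for bd, bv in zip(default.beads, ch2.beads):
        if bd.is_perturbed:
            assert bv.lj_A == (3.4e-5, 7.5e-3)
            assert bv.lj_B == bd.lj_B
        else:
            assert bv == bd


def test_overlapping_geometry_rejected():
    """Geometries whose nonbonded pairs can collide must be refused."""
    from conftest import make_torsion_chain
    from torsionfep.model_system import ZRow, Bead
    base = make_torsion_chain()
    # add a fifth bead placed exactly where the driven bead sits at
    # torsion 0; the (3, 4) pair is nonbonded, so distances reach zero
    bad = retabled(
        base,
        beads=base.beads + [Bead(4, "X", (1e-6, 1e-3), (1e-6, 1e-3),
                                 0.0, 0.0)],
        zmat=base.zmat + [ZRow(2, 1, 0, 0.15, 110.0, -1, 0.0)],
        exclusions={(i, j) for i in range(5) for j in range(i + 1, 5)}
        - {(3, 4)})
    with pytest.raises(ValueError, match="overlap"):
        ms._check_no_overlap(bad)


def test_topology_yaml_round_trip(top):
    text = topology_to_yaml(top)
    back = topology_from_yaml(text)
    assert back.beads == top.beads
    assert back.zmat == top.zmat
    assert back.exclusions == top.exclusions
    assert back.extra_exclusions == top.extra_exclusions
    assert back.torsion_terms == top.torsion_terms
    s = [100.0, -60.0]
    u0, _ = potential_energy(top, s, 0.37)
    u1, _ = potential_energy(back, s, 0.37)
    assert u1 == pytest.approx(u0, rel=1e-12)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_place_beads_round_trip(top, rng):
    """Recomputed torsions equal the input state (inverse kinematics)."""
    for _ in range(25):
        s = rng.uniform(-180.0, 180.0, 2)
        coords = place_beads(top, TorsionState(s))
        back = measure_torsions(top, coords)
        assert np.max(np.abs(wrap_deg(back - s))) < 1e-8


def test_place_beads_periodicity_and_rigidity(top):
    s = np.array([37.0, -115.0])
    c1 = place_beads(top, TorsionState(s))
    c2 = place_beads(top, TorsionState(s + np.array([360.0, -360.0])))
    assert np.allclose(c1, c2, atol=1e-12)
    # bond lengths reproduce the fixed internal geometry
    for (i, j), d in top.bond_lengths.items():
        assert np.linalg.norm(c1[i] - c1[j]) == pytest.approx(d, abs=1e-10)
    # changing psi2 moves only downstream beads (O and N2)
    c3 = place_beads(top, TorsionState([37.0, 40.0]))
    moved = np.where(np.linalg.norm(c1 - c3, axis=1) > 1e-12)[0]
    assert set(moved) == {ms.IDX["O"], ms.IDX["N2"]}


def test_zero_state_round_trips(top):
    coords = place_beads(top, TorsionState([0.0, 0.0]))
    assert np.allclose(measure_torsions(top, coords), 0.0, atol=1e-9)


# ---------------------------------------------------------------------------
# system energy and derivative
# ---------------------------------------------------------------------------

def test_energy_matches_reference_pair_sum(top, sc, rng):
    """Kernel energies equal an independent scalar pair-sum, all variants."""
    ref_sc = ms.reference_softcore()
    for _ in range(20):
        s = rng.uniform(-180.0, 180.0, 2)
        lam = rng.uniform(0.0, 1.0)
        for variant, scc in (("standard", sc), ("extra_exclusions", sc),
                             ("reference_R", ref_sc)):
            u, comps = potential_energy(top, s, lam, scc, variant)
            assert u == pytest.approx(
                reference_energy(top, s, lam, scc, variant), rel=1e-10)
            assert u == pytest.approx(sum(comps.values()), rel=1e-12)


def test_dummy_endpoint_removes_perturbed_bead(top, sc, rng):
    """At lambda=1 the perturbed bead contributes nothing."""
    stripped = retabled(top, beads=[
        dataclasses.replace(b, lj_A=(0.0, 0.0), charge_A=0.0)
        if b.is_perturbed else b for b in top.beads])
    for _ in range(5):
        s = rng.uniform(-180.0, 180.0, 2)
        u1, _ = potential_energy(top, s, 1.0, sc)
        u2, _ = potential_energy(stripped, s, 0.0, sc)
        assert u1 == pytest.approx(u2, rel=1e-12)


def test_exclusion_decomposition(top, sc, rng):
    """U(standard) - U(extra_exclusions) = sum of the four 1,4 pairs."""
    for _ in range(50):
        s = rng.uniform(-180.0, 180.0, 2)
        lam = rng.uniform(0.0, 1.0)
        u_std, _ = potential_energy(top, s, lam, sc)
        u_exc, _ = potential_energy(top, s, lam, sc, "extra_exclusions")
        coords = place_beads(top, TorsionState(s))
        direct = 0.0
        for (i, j) in top.extra_exclusions:
            bi, bj = top.beads[i], top.beads[j]
            r = float(np.linalg.norm(coords[i] - coords[j]))
            direct += softcore_lj(
                r, math.sqrt(bi.lj_A[0] * bj.lj_A[0]),
                math.sqrt(bi.lj_A[1] * bj.lj_A[1]),
                math.sqrt(bi.lj_B[0] * bj.lj_B[0]),
                math.sqrt(bi.lj_B[1] * bj.lj_B[1]), lam, sc)
        assert u_std - u_exc == pytest.approx(direct, rel=1e-9, abs=1e-9)


def test_dudl_matches_finite_differences(top, sc, rng):
    """Analytic dU/dl vs central differences, 1e-6 relative, 1000 draws.

    Draws are restricted to states with |U| <= 1e4 kJ/mol: in harder
    clashes the finite difference itself loses digits to cancellation
    (U ~ 1e5 while dU/dl ~ 1), so no derivative check is meaningful
    there, and such states carry Boltzmann weight exp(-4000).
    """
    h = 1e-6
    done = 0
    while done < 1000:
        s = rng.uniform(-180.0, 180.0, 2)
        lam = rng.uniform(h, 1.0 - h)
        u, _ = potential_energy(top, s, lam, sc)
        if abs(u) > 1e4:
            continue
        a = dU_dlambda(top, s, lam, sc)
        up, _ = potential_energy(top, s, lam + h, sc)
        dn, _ = potential_energy(top, s, lam - h, sc)
        fd = (up - dn) / (2 * h)
        assert abs(a - fd) / max(1.0, abs(a)) < 1e-6
        done += 1


def test_dudl_zero_for_unperturbed_topology(top, sc, rng):
    """A pair identical in both end states contributes no dU/dlambda."""
    frozen = retabled(top, beads=[
        dataclasses.replace(b, lj_B=b.lj_A, charge_B=b.charge_A,
                            is_perturbed=False)
        for b in top.beads])
    for _ in range(5):
        s = rng.uniform(-180.0, 180.0, 2)
        assert dU_dlambda(frozen, s, 0.42, sc) == 0.0
        u0, _ = potential_energy(frozen, s, 0.0, sc)
        u1, _ = potential_energy(frozen, s, 0.77, sc)
        assert u1 == pytest.approx(u0, rel=1e-12)


def test_endpoint_dudl_finite(top, sc, rng):
    for lam in (0.0, 1.0):
        for _ in range(10):
            assert math.isfinite(
                dU_dlambda(top, rng.uniform(-180, 180, 2), lam, sc))


def test_energy_finite_on_coarse_grid(top, sc):
    """U and dU/dl are finite across torsion space at every schedule lambda."""
    grid = np.arange(-180.0, 180.0, 5.0)
    mesh = np.stack(np.meshgrid(grid, grid, indexing="ij"), axis=-1)
    states = mesh.reshape(-1, 2)
    for lam in np.linspace(0, 1, 11):
        U, D = ms.batch_energy(top, states, lam, sc, want_dudl=True)
        assert np.all(np.isfinite(U))
        assert np.all(np.isfinite(D))


def test_lam0_surface_has_two_minima_with_high_barrier(top, sc):
    """The alanine-like surface is bistable with a >=5 kT nonbonded barrier."""
    import scipy.ndimage as ndi
    grid = np.arange(-180.0, 180.0, 2.0)
    mesh = np.stack(np.meshgrid(grid, grid, indexing="ij"), axis=-1)
    states = mesh.reshape(-1, 2)
    U = ms.batch_energy(top, states, 0.0, sc).reshape(len(grid), len(grid))
    is_min = U == ndi.minimum_filter(U, size=11, mode="wrap")
    vals = np.sort(U[is_min])
    assert is_min.sum() >= 2
    # second minimum within a thermally plausible window, separated by a
    # barrier of at least 5 kT along any path (watershed level check)
    second = vals[1]
    lo = U <= second + 5.0 * KT
    lab, n = ndi.label(lo, structure=np.ones((3, 3)))
    # wrap-aware labelling: merge labels across periodic edges
    def merged_components(mask):
        lab, _ = ndi.label(mask, structure=np.ones((3, 3)))
        pairs = set()
        n = len(grid)
        for k in range(n):
            if mask[0, k] and mask[-1, k]:
                pairs.add((lab[0, k], lab[-1, k]))
            if mask[k, 0] and mask[k, -1]:
                pairs.add((lab[k, 0], lab[k, -1]))
        groups = {l: l for l in range(1, lab.max() + 1)}
        def find(x):
            while groups[x] != x:
                x = groups[x]
            return x
        for a, b in pairs:
            groups[find(a)] = find(b)
        return len({find(l) for l in range(1, lab.max() + 1)})
    assert merged_components(lo) >= 2
    # torsional terms alone cannot produce such a barrier: each term's
    # barrier is 2k <= 1 kJ/mol, far below 5 kT
    assert all(2 * k <= 1.0 + 1e-12 for _, k, _, _ in top.torsion_terms)


def test_potential_energy_rejects_unknown_variant(top, sc):
    with pytest.raises(ValueError, match="variant"):
        potential_energy(top, [0.0, 0.0], 0.5, sc, variant="bogus")
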