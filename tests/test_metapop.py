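"""Full metapopulation system: chi, stability matrix, dynamics, patch fates."""

import numpy as np
import pytest

from metanet import (
    ConnectivityMatrix,
    DispersalNetwork,
    HeterogeneousDemographyError,
    Metapopulation,
    PatchDemography,
    connectivity_matrix,
    full_system_matrix,
    generate_regular,
    make_fixture,
    patch_fates,
    persistence_parameter,
    reproductive_number,
    simulate,
    single_patch_persistence,
    spectral_radius,
    stability_matrix,
)
from .conftest import random_dag, random_demography, random_digraph


def _random_metapop(rng, n_max=12, m_max=5):
    net = random_digraph(rng, n=int(rng.integers(2, n_max + 1)))
    demog = random_demography(rng, m=int(rng.integers(1, m_max + 1)))
    eps = float(rng.uniform(0, 0.5))
    conn = connectivity_matrix(net, demog.sigma, eps)
    return Metapopulation(net=net, conn=conn, demography=demog)


class TestPersistenceParameter:
    def test_critical_arithmetic(self):
        """R=2, sigma=0.3, eps=0.1 on a ring (rho(A)=2) sits exactly at chi=1."""
        net = generate_regular(8, 2, seed=0)
        demog = PatchDemography(m=2, survival=(0.5,), fertility=(0.0, 4.0), sigma=0.3)
        mp = Metapopulation(
            net=net, conn=connectivity_matrix(net, 0.3, 0.1), demography=demog
        )
        rep = persistence_parameter(mp)
        assert rep.chi == pytest.approx(1.0, abs=1e-12)
        assert rep.verdict in ("critical", "extinct")
        assert rep.verdict != "persisting"

    def test_acyclic_without_retention_goes_extinct(self, rng):
        net = random_dag(rng)
        demog = random_demography(rng, sigma=0.0)
        mp = Metapopulation(
            net=net, conn=connectivity_matrix(net, 0.0, 0.3), demography=demog
        )
        rep = persistence_parameter(mp)
        assert rep.chi == 0.0 and rep.verdict == "extinct"

    def test_acyclic_with_retention_matches_single_patch(self, rng):
        """Dispersal confers no advantage when no larvae return home."""
        for _ in range(25):
            net = random_dag(rng)
            demog = random_demography(rng)
            mp = Metapopulation(
                net=net,
                conn=connectivity_matrix(net, demog.sigma, float(rng.uniform(0, 0.5))),
                demography=demog,
            )
            chi_single, _ = single_patch_persistence(demog)
            assert persistence_parameter(mp).chi == chi_single

    def test_regular_network_closed_form(self):
        """With sigma = eps on a q-regular network, chi = R sigma (1 + q)."""
        q, sigma = 2, 0.2
        net = generate_regular(10, q, seed=1)
        demog = PatchDemography(m=2, survival=(0.5,), fertility=(0.0, 4.0), sigma=sigma)
        mp = Metapopulation(
            net=net, conn=connectivity_matrix(net, sigma, sigma), demography=demog
        )
        R = reproductive_number(demog)
        assert persistence_parameter(mp).chi == pytest.approx(
            R * sigma * (1 + q), abs=1e-9
        )

    def test_heterogeneous_input_redirected(self, rng):
        net = random_digraph(rng, n=3)
        demogs = [random_demography(rng, m=2) for _ in range(3)]
        mp = Metapopulation(
            net=net, conn=connectivity_matrix(net, 0.3, 0.1), demography=demogs
        )
        with pytest.raises(HeterogeneousDemographyError):
            persistence_parameter(mp)


class TestStabilityMatrix:
    def test_single_patch_reduces_to_leslie(self, rng):
        demog = random_demography(rng, m=3)
        net = DispersalNetwork.from_edges(1, [])
        conn = ConnectivityMatrix(
            C=np.array([[demog.sigma]]), scheme="uniform",
            sigma=demog.sigma, epsilon=0.0,
        )
        mp = Metapopulation(net=net, conn=conn, demography=demog)
        from metanet import build_matrices

        assert stability_matrix(mp) == pytest.approx(
            build_matrices(demog).projection
        )

    def test_scalar_case_eigenvalue_is_chi(self, rng):
        demog = random_demography(rng, m=1)
        net = random_digraph(rng, n=4)
        mp = Metapopulation(
            net=net,
            conn=connectivity_matrix(net, demog.sigma, 0.2),
            demography=demog,
        )
        sm = stability_matrix(mp)
        assert sm.shape == (1, 1)
        assert sm[0, 0] == pytest.approx(persistence_parameter(mp).chi, abs=1e-12)

    def test_matches_full_system_eigenvalue(self, rng):
        """lambda_max of the m x m stability matrix equals lambda_max of the
        full nm x nm system."""
        for _ in range(30):
            mp = _random_metapop(rng)
            lam_small = spectral_radius(stability_matrix(mp))
            lam_full = spectral_radius(full_system_matrix(mp))
            assert lam_small == pytest.approx(lam_full, abs=1e-8)


class TestFullSystemMatrix:
    def test_two_patch_scalar_blocks(self):
        demog = PatchDemography(m=1, survival=(), fertility=(1.5,), sigma=0.4)
        net = DispersalNetwork.from_edges(2, [(0, 1)], directed=False)
        mp = Metapopulation(
            net=net, conn=connectivity_matrix(net, 0.4, 0.2), demography=demog
        )
        f = 1.5
        assert full_system_matrix(mp) == pytest.approx(
            np.array([[0.4 * f, 0.2 * f], [0.2 * f, 0.4 * f]])
        )

    def test_matches_independent_block_assembly(self, rng):
        for _ in range(10):
            mp = _random_metapop(rng, n_max=6, m_max=4)
            from metanet import build_matrices

            mats = build_matrices(mp.demography)
            n, m = mp.n, mp.m
            expected = np.zeros((n * m, n * m))
            for i in range(n):
                for j in range(n):
                    block = mp.conn.C[i, j] * mats.F
                    if i == j:
                        block = block + mats.S
                    expected[i * m:(i + 1) * m, j * m:(j + 1) * m] = block
            assert full_system_matrix(mp) == pytest.approx(expected)

    def test_identical_patches_reduce_to_homogeneous_form(self, rng):
        net = random_digraph(rng, n=4)
        demog = random_demography(rng, m=3)
        conn = connectivity_matrix(net, demog.sigma, 0.2)
        hom = Metapopulation(net=net, conn=conn, demography=demog)
        het = Metapopulation(net=net, conn=conn, demography=[demog] * 4)
        assert full_system_matrix(het) == pytest.approx(full_system_matrix(hom))


class TestSimulate:
    def test_zero_state_stays_zero(self, rng):
        mp = _random_metapop(rng)
        state = simulate(mp, np.zeros((mp.n, mp.m)), T=10)
        assert (state.states == 0).all()
        assert state.growth_estimate == 0.0

    def test_growing_single_patch(self):
        demog = PatchDemography(m=2, survival=(0.5,), fertility=(0.0, 4.0), sigma=0.6)
        net = DispersalNetwork.from_edges(1, [])
        conn = ConnectivityMatrix(C=np.array([[0.6]]), scheme="uniform",
                                  sigma=0.6, epsilon=0.0)
        mp = Metapopulation(net=net, conn=conn, demography=demog)
        assert simulate(mp, np.ones((1, 2)), T=400).growth_estimate > 1.0

    def test_growth_estimate_converges_to_lambda_max(self, rng):
        """With a spectral gap (primitive dominant behaviour) the fitted
        growth factor matches the dominant eigenvalue; gapless/periodic
        systems are excluded, as convergence is only guaranteed with a gap."""
        hits = 0
        for _ in range(30):
            mp = _random_metapop(rng, n_max=8, m_max=4)
            M = full_system_matrix(mp)
            mods = np.sort(np.abs(np.linalg.eigvals(M)))
            lam = mods[-1]
            if lam < 1e-6 or mods[-2] > 0.98 * lam:
                continue
            state = simulate(mp, np.ones((mp.n, mp.m)), T=2000)
            assert state.growth_estimate == pytest.approx(lam, abs=1e-3)
            hits += 1
        assert hits >= 10

    def test_no_overflow_for_strong_growth(self):
        demog = PatchDemography(m=1, survival=(), fertility=(50.0,), sigma=1.0)
        net = DispersalNetwork.from_edges(1, [])
        conn = ConnectivityMatrix(C=np.array([[1.0]]), scheme="uniform",
                                  sigma=1.0, epsilon=0.0)
        mp = Metapopulation(net=net, conn=conn, demography=demog)
        state = simulate(mp, np.ones((1, 1)), T=1000)  # 50^1000 abundances
        assert np.isfinite(state.log_totals).all()
        assert state.growth_estimate == pytest.approx(50.0)


class TestPatchFates:
    def test_all_reachable_patches_persist(self):
        """chi > 1 with every patch downstream of the growing cycle."""
        edges = [(0, 1), (1, 2), (2, 0), (2, 3), (3, 4)]
        net = DispersalNetwork.from_edges(5, edges)
        demog = PatchDemography(m=2, survival=(0.5,), fertility=(0.0, 4.0), sigma=0.3)
        mp = Metapopulation(
            net=net, conn=connectivity_matrix(net, 0.3, 0.4), demography=demog
        )
        rep = persistence_parameter(mp)
        assert rep.chi > 1.0
        assert rep.patch_fates == ("persisting",) * 5

    def test_isolated_sink_goes_extinct(self):
        edges = [(0, 1), (1, 2), (2, 0)]
        net = DispersalNetwork.from_edges(4, edges)  # patch 3 isolated
        demog = PatchDemography(m=2, survival=(0.5,), fertility=(0.0, 4.0), sigma=0.3)
        mp = Metapopulation(
            net=net, conn=connectivity_matrix(net, 0.3, 0.4), demography=demog
        )
        fates = patch_fates(mp)
        assert fates[3] == "extinct"
        assert fates[:3] == ("persisting",) * 3

    def test_all_sources_persist_without_any_network(self):
        net = DispersalNetwork.from_edges(4, [])
        demog = PatchDemography(m=2, survival=(0.5,), fertility=(0.0, 4.0), sigma=0.8)
        mp = Metapopulation(
            net=net, conn=connectivity_matrix(net, 0.8, 0.0), demography=demog
        )
        assert patch_fates(mp) == ("persisting",) * 4

    def test_persisting_patches_hold_abundance_share(self):
        """Simulated relative abundance stays bounded away from zero on
        persisting patches and vanishes on unreachable extinct ones."""
        edges = [(0, 1), (1, 2), (2, 0), (2, 3)]
        net = DispersalNetwork.from_edges(5, edges)  # patch 4 disconnected
        demog = PatchDemography(m=2, survival=(0.5,), fertility=(0.0, 4.0), sigma=0.3)
        mp = Metapopulation(
            net=net, conn=connectivity_matrix(net, 0.3, 0.4), demography=demog
        )
        fates = patch_fates(mp)
        assert fates == ("persisting",) * 4 + ("extinct",)
        state = simulate(mp, np.ones((5, 2)), T=500)
        shares = state.states[-1].sum(axis=1)
        assert (shares[:4] > 1e-6).all()
        assert shares[4] < 1e-12


class TestCentralTheorem:
    def test_chi_eigenvalue_and_simulation_agree(self, rng):
        """The three routes to the persistence verdict coincide: chi vs 1,
        lambda_max of the full system vs 1, and simulated growth vs 1."""
        checked = 0
        for _ in range(60):
            mp = _random_metapop(rng)
            rep = persistence_parameter(mp)
            if abs(rep.chi - 1.0) < 1e-6:
                continue
            assert (rep.chi > 1.0) == (rep.lambda_max > 1.0)
            checked += 1
        assert checked >= 50

    def test_bootstrap_instance_all_sinks_yet_growing(self):
        """Every patch a sink in isolation, yet subsidy recruitment pushes
        the metapopulation over the threshold and simulation grows."""
        fx = make_fixture("bootstrap_sinks", seed=0)
        net = fx["net"]
        demog = PatchDemography.from_dict(fx["config"]["demography"])
        chi_single, label = single_patch_persistence(demog)
        assert label == "sink" and chi_single < 1.0
        mp = Metapopulation(
            net=net,
            conn=connectivity_matrix(
                net, fx["config"]["sigma"], fx["config"]["epsilon"]
            ),
            demography=demog,
        )
        rep = persistence_parameter(mp)
        assert rep.chi > 1.0 and rep.verdict == "persisting"
        state = simulate(mp, np.ones((net.n, 2)), T=400)
        assert state.growth_estimate > 1.0
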