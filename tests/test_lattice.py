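import numpy as np
import pytest

from aplg.params import ModelParams
from aplg import lattice


def consistent(state):
    """Exclusion + bookkeeping invariant: every particle sits alone on its
    recorded site and the grid holds nothing else."""
    n = len(state.species)
    occupied = state.grid >= 0
    if occupied.sum() != n:
        return False
    return all(state.grid[state.xs[k], state.ys[k]] == k for k in range(n))


class TestInitialize:
    def test_empty_lattice(self):
        p = ModelParams(Pe=5.0, L=2.0, phi_a=0.0, phi_p=0.0, h=0.05)
        st = lattice.initialize_lattice(p, dims=(40, 10), seed=0)
        assert len(st.species) == 0
        assert np.all(st.grid == -1)

    def test_binomial_counts(self):
        p = ModelParams(Pe=5.0, L=5.0, phi_a=0.5, phi_p=0.1, h=0.025)
        st = lattice.initialize_lattice(p, dims=(200, 50), seed=1)
        n_sites = 200 * 50
        counts = st.counts()
        n_act = counts["right"] + counts["left"]
        # 4 sigma of Binomial(10000, 0.5)
        assert abs(n_act - 0.5 * n_sites) < 4 * np.sqrt(n_sites * 0.25)
        assert abs(counts["passive"] - 0.1 * n_sites) < 4 * np.sqrt(
            n_sites * 0.1 * 0.9
        )

    def test_seed_determinism(self):
        p = ModelParams(Pe=5.0, L=2.0, phi_a=0.3, phi_p=0.2, h=0.05)
        a = lattice.initialize_lattice(p, dims=(40, 10), seed=7)
        b = lattice.initialize_lattice(p, dims=(40, 10), seed=7)
        assert np.array_equal(a.occupancy(), b.occupancy())

    def test_too_coarse_spacing_rejected(self):
        p = ModelParams(Pe=20.0, L=2.0, phi_a=0.3, phi_p=0.2, h=0.15)
        with pytest.raises(ValueError, match="h"):
            lattice.initialize_lattice(p, dims=(13, 4), seed=0)


class TestSiteRates:
    @pytest.fixture()
    def small_state(self):
        p = ModelParams(Pe=8.0, L=1.0, phi_a=0.5, phi_p=0.3, h=0.1)
        return p, lattice.initialize_lattice(p, dims=(10, 10), seed=3)

    def test_passive_rates(self, small_state):
        p, st = small_state
        k = np.nonzero(st.species == lattice.PASSIVE)[0][0]
        site = (st.xs[k], st.ys[k])
        ev = lattice.site_rates(st, site, p)
        assert len(ev) == 4
        assert all(r == pytest.approx(1.0 / 0.1**2) for _, r in ev)

    def test_active_rates(self, small_state):
        p, st = small_state
        k = np.nonzero(st.species == lattice.RIGHT)[0][0]
        ev = dict(lattice.site_rates(st, (st.xs[k], st.ys[k]), p))
        base = 1.0 / 0.1**2
        assert ev["jump_right"] == pytest.approx(base + 8.0 / (2 * 0.1))
        assert ev["jump_left"] == pytest.approx(base - 8.0 / (2 * 0.1))
        assert ev["jump_up"] == pytest.approx(base)
        assert ev["flip"] == pytest.approx(1.0)

    def test_empty_site_raises(self, small_state):
        p, st = small_state
        empty = tuple(np.argwhere(st.grid == -1)[0])
        with pytest.raises(ValueError):
            lattice.site_rates(st, empty, p)


class TestGillespie:
    def test_species_conservation_and_exclusion(self):
        p = ModelParams(Pe=10.0, L=2.0, phi_a=0.4, phi_p=0.2, h=0.05)
        st = lattice.initialize_lattice(p, dims=(40, 10), seed=2)
        before = st.counts()
        before_act = before["right"] + before["left"]
        lattice.gillespie_run(st, 0.5, p, seed=5)
        after = st.counts()
        assert after["right"] + after["left"] == before_act
        assert after["passive"] == before["passive"]
        assert consistent(st)

    def test_single_passive_particle_diffusion(self):
        """Mean-squared x-displacement of a lone passive walker is 2t."""
        h = 0.1
        p = ModelParams(Pe=0.0, L=6.4, phi_a=0.0, phi_p=0.0, h=h)
        n_rep, t = 1500, 0.4
        sq = []
        nx = 64
        for rep in range(n_rep):
            grid = np.full((nx, nx), -1, dtype=np.int64)
            grid[32, 32] = 0
            st = lattice.LatticeState(
                grid=grid, species=np.array([lattice.PASSIVE], dtype=np.int8),
                xs=np.array([32]), ys=np.array([32]), h=h,
            )
            lattice.gillespie_run(st, t, p, seed=1000 + rep)
            dx = (st.xs[0] - 32 + nx // 2) % nx - nx // 2
            sq.append((dx * h) ** 2)
        msd = np.mean(sq)
        # Var of the estimate ~ (2t)^2 * 2 / n  -> 4 sigma band
        assert msd == pytest.approx(2 * t, abs=4 * 2 * t * np.sqrt(2 / n_rep))

    def test_orientation_correlation_decay(self):
        """A lone active particle's orientation decorrelates as exp(-2t):
        P(same orientation at t) = (1 + e^(-2t))/2 for unit flip rate."""
        h = 0.1
        p = ModelParams(Pe=0.0, L=3.2, phi_a=0.0, phi_p=0.0, h=h)
        n_rep, t = 2000, 0.5
        same = 0
        for rep in range(n_rep):
            grid = np.full((32, 32), -1, dtype=np.int64)
            grid[16, 16] = 0
            st = lattice.LatticeState(
                grid=grid, species=np.array([lattice.RIGHT], dtype=np.int8),
                xs=np.array([16]), ys=np.array([16]), h=h,
            )
            lattice.gillespie_run(st, t, p, seed=3000 + rep)
            same += st.species[0] == lattice.RIGHT
        expected = 0.5 * (1 + np.exp(-2 * t))
        sigma = np.sqrt(expected * (1 - expected) / n_rep)
        assert same / n_rep == pytest.approx(expected, abs=4 * sigma)


class TestMesoscopicDensity:
    def test_full_lattice_density_one(self):
        p = ModelParams(Pe=0.0, L=2.0, phi_a=0.0, phi_p=1.0, h=0.05)
        st = lattice.initialize_lattice(p, dims=(40, 10), seed=0)
        d = lattice.mesoscopic_density(st, r=0.1)
        assert np.allclose(d["rho"], 1.0)

    def test_homogeneous_mean_and_smoothing(self):
        p = ModelParams(Pe=0.0, L=10.0, phi_a=0.4, phi_p=0.2, h=0.05)
        st = lattice.initialize_lattice(p, dims=(200, 50), seed=4)
        d1 = lattice.mesoscopic_density(st, r=0.1)
        d2 = lattice.mesoscopic_density(st, r=0.5)
        assert d1["rho"].mean() == pytest.approx(0.6, abs=0.02)
        # wider window -> smaller fluctuations around the mean
        assert d2["rho"].std() < d1["rho"].std()

    def test_total_mass_preserved_by_smoothing(self):
        p = ModelParams(Pe=0.0, L=4.0, phi_a=0.3, phi_p=0.3, h=0.05)
        st = lattice.initialize_lattice(p, dims=(80, 20), seed=5)
        d = lattice.mesoscopic_density(st, r=0.2)
        n_act = (st.species != lattice.PASSIVE).sum()
        frac = n_act / (80 * 20)
        assert (d["plus"] + d["minus"]).mean() == pytest.approx(frac, abs=1e-12)

    def test_window_smaller_than_site_rejected(self):
        p = ModelParams(Pe=0.0, L=2.0, phi_a=0.2, phi_p=0.2, h=0.05)
        st = lattice.initialize_lattice(p, dims=(40, 10), seed=0)
        with pytest.raises(ValueError):
            lattice.mesoscopic_density(st, r=0.01)
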