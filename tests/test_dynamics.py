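"""Event kernels: rate functions, growth, conjugation, culling."""

import math

import numpy as np
import pytest
from scipy import stats

from plasmidlattice import (
    CellType,
    Lattice,
    MutationLocus,
    SimulationParams,
    SiteState,
    attempt_conjugation,
    attempt_growth,
    conjugation_rate,
    cull,
    growth_rate,
)
from plasmidlattice.dynamics import EventKind


class TestRateFunctions:
    @pytest.mark.parametrize(
        "C, psi_max, theta, expected",
        [
            (0.9, 1.0, 0.8, 1.0),  # saturated branch
            (0.0, 1.0, 0.8, 0.0),  # no nutrients
            (0.4, 0.8, 0.8, 0.4),  # linear branch: 0.8·0.4/0.8
            (0.8, 1.0, 0.8, 1.0),  # exactly at threshold
            (1.0, 0.6, 0.8, 0.6),
        ],
    )
    def test_growth_rate_piecewise(self, C, psi_max, theta, expected):
        assert growth_rate(C, psi_max, theta) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "C, gamma_max, expected",
        [
            (0.1, 1.0, 0.0),  # below theta1
            (0.5, 0.01, 0.01),  # saturated
            (0.25, 1.0, 0.5),  # midpoint of the linear ramp
            (0.2, 1.0, 0.0),  # exactly at theta1
            (0.3, 1.0, 1.0),  # exactly at theta2
            (0.0, 1.0, 0.0),
            (1.0, 0.1, 0.1),
        ],
    )
    def test_conjugation_rate_piecewise(self, C, gamma_max, expected):
        assert conjugation_rate(C, gamma_max, 0.2, 0.3) == pytest.approx(expected, abs=1e-15)

    def test_continuity_at_thresholds(self):
        eps = 1e-14
        for theta in (0.5, 0.8):
            assert abs(growth_rate(theta - eps, 1.0, theta) - growth_rate(theta, 1.0, theta)) < 1e-12
        for t1, t2 in ((0.2, 0.3), (0.1, 0.7)):
            for edge in (t1, t2):
                lo = conjugation_rate(edge - eps, 1.0, t1, t2)
                hi = conjugation_rate(edge, 1.0, t1, t2)
                assert abs(lo - hi) < 1e-12

    def test_monotone_nondecreasing_in_C(self):
        grid = np.linspace(0, 1, 201)
        g = [growth_rate(x, 1.0, 0.8) for x in grid]
        c = [conjugation_rate(x, 1.0, 0.2, 0.3) for x in grid]
        assert all(b >= a for a, b in zip(g, g[1:]))
        assert all(b >= a for a, b in zip(c, c[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            growth_rate(1.5, 1.0, 0.8)
        with pytest.raises(ValueError):
            growth_rate(-0.1, 1.0, 0.8)
        with pytest.raises(ValueError):
            conjugation_rate(0.5, 1.0, 0.4, 0.3)


def _params(**kw):
    defaults = dict(edge=20, n_donors=1, n_recipients=1, b=0.4, c=0.1, adaptation_time=70)
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestAttemptGrowth:
    def test_no_empty_neighbor_is_noop(self, placer, scripted_rng):
        lat = Lattice(20)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                placer(lat, 10 + dx, 10 + dy, CellType.RECIPIENT)
        rng = scripted_rng([])  # no draws may be consumed
        out = attempt_growth(lat, (10, 10), _params(), rng)
        assert out.kind is EventKind.NONE
        assert rng.used == 0

    def test_empty_focal_rejected(self, scripted_rng):
        lat = Lattice(20)
        with pytest.raises(ValueError):
            attempt_growth(lat, (5, 5), _params(), scripted_rng([]))

    def test_nonadapted_transconjugant_birth_decrements_countdown(self, placer, scripted_rng):
        """A lone non-adapted transconjugant (b=0.4) sees C≈0.98 ≥ θ, so ψ = 0.6;
        u=0.5 accepts, and the division costs one countdown unit on both cells."""
        lat = Lattice(20)
        placer(lat, 10, 10, CellType.TRANSCONJUGANT, cost=0.4, countdown=70)
        rng = scripted_rng([0.5, 0.0, 0.9])  # accept, slot 0, no segregation
        out = attempt_growth(lat, (10, 10), _params(b=0.4), rng)
        assert out.kind is EventKind.BIRTH
        parent = lat.state(10, 10)
        daughter = lat.state(*out.details["daughter"])
        for cell in (parent, daughter):
            assert cell.cell_type is CellType.TRANSCONJUGANT
            assert cell.plasmid_cost == 0.4
            assert cell.countdown == 69

    def test_growth_rejected_when_u_exceeds_rate(self, placer, scripted_rng):
        lat = Lattice(20)
        placer(lat, 10, 10, CellType.TRANSCONJUGANT, cost=0.4, countdown=70)
        out = attempt_growth(lat, (10, 10), _params(), scripted_rng([0.61]))
        assert out.kind is EventKind.NONE
        assert lat.occupied_count == 1

    def test_final_division_ameliorates_both_cells(self, placer, scripted_rng):
        """countdown=1 → after the division both cells are adapted at cost c."""
        lat = Lattice(20)
        placer(lat, 10, 10, CellType.TRANSCONJUGANT, cost=0.4, countdown=1)
        out = attempt_growth(lat, (10, 10), _params(c=0.1), scripted_rng([0.1, 0.0, 0.9]))
        assert out.kind is EventKind.BIRTH
        for cell in (lat.state(10, 10), lat.state(*out.details["daughter"])):
            assert cell.countdown == 0
            assert cell.plasmid_cost == 0.1

    @pytest.mark.parametrize(
        "ptype, cost, cd, seg_type",
        [
            (CellType.DONOR, 0.1, 0, CellType.SEG_DONOR),
            (CellType.TRANSCONJUGANT, 0.1, 0, CellType.SEG_ADAPTED),
            (CellType.TRANSCONJUGANT, 0.4, 50, CellType.SEG_NONADAPTED),
        ],
    )
    def test_segregant_daughter_types(self, placer, scripted_rng, ptype, cost, cd, seg_type):
        lat = Lattice(20)
        placer(lat, 10, 10, ptype, cost=cost, countdown=cd)
        rng = scripted_rng([0.1, 0.0, 0.0005])  # segregation fires (≤ 0.001)
        out = attempt_growth(lat, (10, 10), _params(), rng)
        daughter = lat.state(*out.details["daughter"])
        assert daughter.cell_type is seg_type
        assert daughter.plasmid_cost == 0.0
        assert daughter.countdown == 0

    def test_plasmid_free_parent_consumes_no_segregation_draw(self, placer, scripted_rng):
        lat = Lattice(20)
        placer(lat, 10, 10, CellType.RECIPIENT)
        rng = scripted_rng([0.1, 0.0])
        out = attempt_growth(lat, (10, 10), _params(), rng)
        assert out.kind is EventKind.BIRTH
        assert rng.used == 2

    def test_never_overwrites_occupied_site(self, placer):
        """Many repeated births from a crowded cluster never clobber a cell."""
        rng = np.random.RandomState(0)
        lat = Lattice(10)
        for k in range(5):
            lat.set_state(4 + k % 2, 4 + k // 2, SiteState(CellType.RECIPIENT))
        for _ in range(200):
            occ = lat.occupied_sites[: lat.occupied_count].copy()
            before = lat.occupied_count
            site = lat.coords(int(occ[rng.randint(before)]))
            attempt_growth(lat, site, _params(), rng)
            assert lat.occupied_count in (before, before + 1)
            # previously occupied sites are all still occupied
            assert np.all(lat.types[occ] != 0)
        lat.check_consistency()


class TestAttemptConjugation:
    def test_no_plasmid_free_neighbor_is_noop(self, placer, scripted_rng):
        lat = Lattice(20)
        placer(lat, 10, 10, CellType.DONOR, cost=0.1)
        placer(lat, 10, 11, CellType.TRANSCONJUGANT, cost=0.4, countdown=70)
        rng = scripted_rng([])
        assert attempt_conjugation(lat, (10, 10), _params(), rng).kind is EventKind.NONE
        assert rng.used == 0

    def test_plasmid_free_focal_rejected(self, placer, scripted_rng):
        lat = Lattice(20)
        placer(lat, 10, 10, CellType.RECIPIENT)
        with pytest.raises(ValueError):
            attempt_conjugation(lat, (10, 10), _params(), scripted_rng([]))

    def test_donor_transfers_costly_plasmid_with_full_countdown(self, placer, scripted_rng):
        lat = Lattice(20)
        placer(lat, 10, 10, CellType.DONOR, cost=0.1)
        placer(lat, 10, 11, CellType.RECIPIENT)
        out = attempt_conjugation(lat, (10, 10), _params(), scripted_rng([0.5, 0.0]))
        assert out.kind is EventKind.CONJUGATION
        t = lat.state(10, 11)
        assert t.cell_type is CellType.TRANSCONJUGANT
        assert t.plasmid_cost == 0.4
        assert t.countdown == 70

    def test_adapted_source_modes_diverge(self, placer, scripted_rng):
        """The same adapted-transconjugant transfer gives an adapted plasmid in
        plasmid-locus mode but a naive (cost b, full countdown) transconjugant
        in chromosome-locus mode."""
        results = {}
        for mode in MutationLocus:
            lat = Lattice(20)
            lat.set_state(10, 10, SiteState(CellType.TRANSCONJUGANT, 0.1, 0))
            lat.set_state(10, 11, SiteState(CellType.RECIPIENT))
            params = _params(mutation_locus=mode)
            attempt_conjugation(lat, (10, 10), params, scripted_rng([0.5, 0.0]))
            results[mode] = lat.state(10, 11)
        assert results[MutationLocus.PLASMID] == SiteState(CellType.TRANSCONJUGANT, 0.1, 0)
        assert results[MutationLocus.CHROMOSOME] == SiteState(CellType.TRANSCONJUGANT, 0.4, 70)

    def test_plasmid_mode_inherits_partial_countdown(self, placer, scripted_rng):
        lat = Lattice(20)
        lat.set_state(10, 10, SiteState(CellType.TRANSCONJUGANT, 0.4, 33))
        lat.set_state(10, 11, SiteState(CellType.RECIPIENT))
        params = _params(mutation_locus=MutationLocus.PLASMID)
        attempt_conjugation(lat, (10, 10), params, scripted_rng([0.5, 0.0]))
        assert lat.state(10, 11) == SiteState(CellType.TRANSCONJUGANT, 0.4, 33)

    @pytest.mark.parametrize("mode", list(MutationLocus))
    def test_donor_segregant_target_becomes_donor_again(self, placer, scripted_rng, mode):
        lat = Lattice(20)
        lat.set_state(10, 10, SiteState(CellType.DONOR, 0.1, 0))
        lat.set_state(10, 11, SiteState(CellType.SEG_DONOR))
        attempt_conjugation(lat, (10, 10), _params(mutation_locus=mode), scripted_rng([0.5, 0.0]))
        assert lat.state(10, 11) == SiteState(CellType.DONOR, 0.1, 0)

    def test_chromosome_adapted_segregant_resumes_adapted(self, placer, scripted_rng):
        lat = Lattice(20)
        lat.set_state(10, 10, SiteState(CellType.DONOR, 0.1, 0))
        lat.set_state(10, 11, SiteState(CellType.SEG_ADAPTED))
        params = _params(mutation_locus=MutationLocus.CHROMOSOME)
        attempt_conjugation(lat, (10, 10), params, scripted_rng([0.5, 0.0]))
        assert lat.state(10, 11) == SiteState(CellType.TRANSCONJUGANT, 0.1, 0)

    def test_occupancy_never_changes(self, placer, scripted_rng):
        lat = Lattice(20)
        placer(lat, 10, 10, CellType.DONOR, cost=0.1)
        placer(lat, 10, 11, CellType.RECIPIENT)
        before = lat.occupied_count
        attempt_conjugation(lat, (10, 10), _params(), scripted_rng([0.5, 0.0]))
        assert lat.occupied_count == before
        lat.check_consistency()


class TestCull:
    def _full_lattice(self, edge=20, donor_fraction=0.5):
        lat = Lattice(edge)
        params = SimulationParams(
            edge=edge, n_donors=1, n_recipients=1, n_cull_events=0
        )
        n_fill = params.fill_threshold
        n_donor = int(n_fill * donor_fraction)
        for s in range(n_fill):
            x, y = divmod(s, edge)
            if s < n_donor:
                lat.set_state(x, y, SiteState(CellType.DONOR, 0.0, 0))
            else:
                lat.set_state(x, y, SiteState(CellType.RECIPIENT))
        return lat, params, n_donor

    def test_exact_target_occupancy(self):
        lat, params, _ = self._full_lattice()
        cull(lat, params, np.random.RandomState(0))
        assert lat.occupied_count == params.cull_target
        lat.check_consistency()

    def test_below_threshold_rejected(self, small_params):
        lat = Lattice(20)
        lat.set_state(0, 0, SiteState(CellType.RECIPIENT))
        with pytest.raises(ValueError):
            cull(lat, SimulationParams(edge=20, n_donors=1, n_recipients=1), np.random.RandomState(0))

    def test_type_blind_survival_matches_hypergeometric(self):
        """Donor survivor counts over 100 repeated culls of the same lattice are
        consistent with sampling survivors uniformly without replacement."""
        lat, params, n_donor = self._full_lattice(edge=20, donor_fraction=0.5)
        n_fill, target = params.fill_threshold, params.cull_target
        rng = np.random.RandomState(12345)
        survivors = []
        for _ in range(100):
            trial = lat.copy()
            cull(trial, params, rng)
            survivors.append(int(trial.type_counts[int(CellType.DONOR)]))
        hg = stats.hypergeom(n_fill, n_donor, target)
        # integer quintile edges; cdf evaluated at integers, histogram at k+0.5
        edges = hg.ppf([0.2, 0.4, 0.6, 0.8]).astype(int)
        observed, _ = np.histogram(
            survivors, bins=np.concatenate([[-0.5], edges + 0.5, [n_donor + 0.5]])
        )
        cdf_points = np.concatenate([[-1], edges, [n_donor]])
        expected = np.diff(hg.cdf(cdf_points)) * 100
        _, p = stats.chisquare(observed, expected / expected.sum() * observed.sum())
        assert p > 0.01
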