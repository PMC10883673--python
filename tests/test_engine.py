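"""Stochastic engine: determinism, limiting cases, oracle equivalence,
conservation, catastrophe rule, rate switching and census."""

import numpy as np
import pytest
from scipy import stats

from ebtip.engine import (
    SimulationConfig,
    apply_catastrophe_rule,
    census,
    run,
)
from ebtip.kinetics import KineticParameters
from ebtip.lattice import Lattice
from ebtip.reference import run_occupancy, step
from tests.conftest import eb1_only_params


def test_seeded_runs_are_identical():
    cfg = lambda: SimulationConfig(n_steps=20_000, rng_seed=42, max_sim_time=60.0)
    a, b = run(cfg()), run(cfg())
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.lengths, b.lengths)
    assert np.array_equal(a.tallies, b.tallies)
    assert np.array_equal(a.bound_j, b.bound_j)
    c = run(SimulationConfig(n_steps=20_000, rng_seed=43, max_sim_time=60.0))
    assert not np.array_equal(a.lengths[-1], c.lengths[-1])


def test_growth_only_limit():
    """With EB1 binding, tubulin departure and hydrolysis all off, the only
    feasible events are arrivals and bond formation: lengths never decrease
    and the nucleotide map stays all-GTP."""
    zero_tab = {(n, b): 0.0 for n in ("GTP", "GDP") for b in range(3)}
    p = KineticParameters(
        k_off_tubulin_base=zero_tab, k_hydrolysis=0.0, k_lat_break_base=0.0,
        k_on_edge=0.0, k_on_closed=0.0,
    )
    traj = run(SimulationConfig(params=p, n_steps=20_000, rng_seed=7))
    assert (np.diff(traj.lengths.astype(int), axis=0) >= 0).all()
    t = traj.tallies_dict()
    assert t["tubulin_off"] == t["eb1_on_edge"] == t["eb1_on_closed"] == 0
    assert t["hydrolysis"] == 0
    assert traj.final_state["gdp"].sum() == 0


def test_no_hydrolysis_keeps_gtp_map_full():
    p = KineticParameters(k_hydrolysis=0.0)
    traj = run(SimulationConfig(params=p, n_steps=30_000, rng_seed=3))
    # every non-seed dimer is recorded as GTP in the last snapshot
    snap = traj.snapshot(traj.n_snapshots - 1)
    n_nonseed = int((snap["lengths"] - traj.config.seed_length).sum())
    assert len(snap["gtp_j"]) == n_nonseed


def test_zero_on_rates_give_zero_binding_events():
    p = KineticParameters(k_on_edge=0.0, k_on_closed=0.0)
    traj = run(SimulationConfig(params=p, n_steps=30_000, rng_seed=5))
    t = traj.tallies_dict()
    assert t["eb1_on_edge"] == 0 and t["eb1_on_closed"] == 0
    assert traj.bound_counts.sum() == 0


def test_occupancy_conservation():
    traj = run(SimulationConfig(n_steps=60_000, rng_seed=11, max_sim_time=120.0))
    t = traj.final_state["tallies"]  # end-of-run tallies
    bound_now = int(traj.final_state["occ"].sum())
    assert bound_now == t[4] + t[5] - t[6] - t[7]
    # and at every recording step
    for k in range(traj.n_snapshots):
        tk = traj.tallies[k]
        assert traj.bound_counts[k].sum() == tk[4] + tk[5] - tk[6] - tk[7]


def test_incremental_classification_matches_from_scratch():
    """The kernel's incrementally maintained site classes equal a fresh
    pure-python reclassification of the final lattice state."""
    traj = run(SimulationConfig(n_steps=40_000, rng_seed=13, max_sim_time=90.0))
    st = traj.final_state
    n_pf, cap = st["gdp"].shape
    lat = Lattice(n_pf=n_pf, seed_length=traj.config.seed_length, capacity=cap)
    lat.length = st["length"].copy()
    lat.gdp = st["gdp"].copy()
    lat.bond = st["bond"].copy()
    lat.occ = st["occ"].copy()
    lat.origin = st["origin"].copy()
    expected = {}
    for s in lat.iter_sites():
        expected[(s.interface, s.j)] = 1 if s.structural_class == "edge" else 2
    cached = {}
    site_state = st["site_state"]
    for i in range(n_pf):
        for j in range(cap):
            if site_state[i, j]:
                cached[(i, j)] = int(site_state[i, j])
    assert cached == expected


class TestOracleEquivalence:
    """First-reaction engine vs the literal per-candidate reference and the
    closed-form equilibrium, on a frozen small lattice with EB1 only."""

    def frozen_params(self):
        return eb1_only_params()

    def test_kernel_matches_closed_form(self):
        p = self.frozen_params()
        kon_c = p.k_on_closed * p.eb1_conc
        occ_c = kon_c / (kon_c + p.k_off_closed_GTP)
        kon_e = p.k_on_edge * p.eb1_conc
        occ_e = kon_e / (kon_e + p.k_off_edge_GTP)
        # 3 circular protofilaments x 10 seed dimers: 27 closed + 3 edge pockets
        expected = 27 * occ_c + 3 * occ_e
        means = []
        for seed in range(6):
            traj = run(
                SimulationConfig(
                    params=p, n_steps=120_000, rng_seed=seed, n_pf=3,
                    seed_length=10, capacity=32, record_interval=200,
                )
            )
            burn = traj.n_snapshots // 3
            means.append(traj.bound_counts[burn:].sum(axis=1).mean())
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - expected) < 3 * se + 0.05

    def test_reference_engine_matches_closed_form(self, rng):
        p = self.frozen_params()
        lat = Lattice(n_pf=3, seed_length=10, capacity=32)
        mean_occ, site_frac = run_occupancy(lat, p, rng, n_steps=6000)
        kon_c = p.k_on_closed * p.eb1_conc
        occ_c = kon_c / (kon_c + p.k_off_closed_GTP)
        kon_e = p.k_on_edge * p.eb1_conc
        occ_e = kon_e / (kon_e + p.k_off_edge_GTP)
        expected = 27 * occ_c + 3 * occ_e
        assert mean_occ == pytest.approx(expected, rel=0.15)

    def test_fast_candidate_dominates_first_reaction(self, rng):
        """With one candidate vastly faster than the rest, it wins
        essentially always (competing exponentials)."""
        p = eb1_only_params(k_off_closed_GTP=1e6, k_on_edge=0.0)
        wins = 0
        for _ in range(40):
            lat = Lattice(n_pf=3, seed_length=10, capacity=32)
            lat.occ[0, 0] = 1
            lat.origin[0, 0] = 2
            res = step(lat, p, rng)
            wins += res.event.kind.value == "eb1_off"
        assert wins == 40


def test_uniform_density_without_hydrolysis(rng):
    """All-GTP frozen lattice with equal edge/closed rates: time-averaged
    EB1 positions are longitudinally uniform (no tip tracking)."""
    p = eb1_only_params(
        k_on_edge=4.7e-4, k_on_closed=4.7e-4,
        k_off_closed_GTP=0.5, k_off_closed_GDP=0.5,
        k_off_edge_GTP=0.5, k_off_edge_GDP=0.5,
    )
    counts = np.zeros(40)
    for seed in range(3):
        traj = run(
            SimulationConfig(params=p, n_steps=150_000, rng_seed=seed, n_pf=13,
                             seed_length=40, capacity=64, record_interval=300)
        )
        burn = traj.n_snapshots // 3
        a = traj.bound_offsets[burn]
        js = traj.bound_j[a:]
        counts += np.bincount(js, minlength=40)[:40]
    assert counts.sum() > 2000
    chi = stats.chisquare(counts)
    assert chi.pvalue > 0.01


def test_catastrophe_rule_threshold(params):
    lengths = np.full(13, 25)
    lengths[0] = 25 + 74  # taper 592 nm
    assert not apply_catastrophe_rule(lengths, params)
    lengths[0] = 25 + 76  # taper 608 nm
    assert apply_catastrophe_rule(lengths, params)
    split = params.with_overrides(max_taper_dimers=400)
    lengths[0] = 25 + 125  # 1000 nm, below the split-comet cap (~3.2 um)
    assert not apply_catastrophe_rule(lengths, split)


def test_rate_switch_silences_edge_binding():
    schedule = [(20.0, "k_on_edge", 0.0), (45.0, "k_on_edge", 4.7e-3)]
    traj = run(
        SimulationConfig(n_steps=120_000, rng_seed=21, max_sim_time=80.0,
                         rate_switch_schedule=schedule)
    )
    inside = (traj.times > 22.0) & (traj.times < 44.0)
    idx = np.nonzero(inside)[0]
    assert idx.size >= 2
    d_edge = traj.tallies[idx[-1], 4] - traj.tallies[idx[0], 4]
    assert d_edge == 0
    after = np.nonzero(traj.times > 50.0)[0]
    assert traj.tallies[after[-1], 4] > traj.tallies[after[0], 4]


def test_invalid_switch_target_rejected():
    from ebtip.lattice import ConfigurationError

    with pytest.raises(ConfigurationError):
        SimulationConfig(rate_switch_schedule=[(1.0, "k_on_egde", 0.0)])


def test_census_all_edge_when_closed_rate_zero():
    p = KineticParameters(k_on_closed=0.0)
    traj = run(SimulationConfig(params=p, n_steps=40_000, rng_seed=9))
    c = census(traj)
    assert c["edge_binding_fraction"] == 1.0
    assert c["n_binding_events"] > 0
    assert census(traj, at_time=0.0)["n_binding_events"] <= c["n_binding_events"]


def test_trajectory_roundtrip(tmp_path):
    traj = run(SimulationConfig(n_steps=15_000, rng_seed=2, max_sim_time=40.0))
    path = tmp_path / "run.h5"
    traj.to_hdf5(path)
    back = traj.from_hdf5(path)
    assert np.array_equal(back.lengths, traj.lengths)
    assert np.array_equal(back.tallies, traj.tallies)
    assert back.config.params.eb1_conc == traj.config.params.eb1_conc
    assert back.status == traj.status
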