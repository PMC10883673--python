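"""Literal per-candidate first-reaction engine.

This implementation enumerates every candidate event each step, draws an
independent exponential waiting time per candidate with ``-log(u) / k``, and
executes the single candidate with the shortest time, followed by the
hydrolysis sub-step.  It is O(number of candidates) per step and intended
for small lattices: step-level semantics, oracle-equivalence tests against
the production kernel, and didactic use.  The production engine
(:mod:`ebtip.engine`) samples the same joint law in aggregate form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    KineticParameters,
    draw_event_time,
    eb1_off_rate,
    eb1_on_rate,
    lateral_bond_rates,
    tubulin_arrival_rate,
    tubulin_off_rate,
)
from .lattice import Event, EventKind, Lattice


@dataclass
class StepResult:
    event: Event
    dt: float
    hydrolyzed: tuple[int, int] | None
    forced_releases: list[tuple[int, int]]


def enumerate_candidates(
    lattice: Lattice, params: KineticParameters, boosted: bool = False
) -> list[tuple[Event, float]]:
    """All feasible (event, rate) pairs in the current state.

    Events with zero rate are not candidates and are never sampled.
    """
    out: list[tuple[Event, float]] = []
    arr = tubulin_arrival_rate(params)
    k_form, k_break = lateral_bond_rates(params, boosted)
    for p in range(lattice.n_pf):
        if arr > 0:
            out.append((Event(EventKind.TUBULIN_ON, pf=p), arr))
        h = int(lattice.length[p]) - 1
        if h >= lattice.seed_length:
            left = (p - 1) % lattice.n_pf
            nb = int(lattice.bond[left, h]) + int(lattice.bond[p, h])
            nuc = "GDP" if lattice.gdp[p, h] else "GTP"
            k = tubulin_off_rate(nuc, nb, boosted, params)
            if k > 0:
                out.append((Event(EventKind.TUBULIN_OFF, pf=p), k))
    for i in range(lattice.n_pf):
        r = lattice.right_neighbor(i)
        lo = int(min(lattice.length[i], lattice.length[r]))
        for j in range(lo):
            if lattice.bond[i, j]:
                if k_break > 0:
                    out.append((Event(EventKind.LAT_BREAK, interface=i, j=j), k_break))
            elif k_form > 0:
                out.append((Event(EventKind.LAT_FORM, interface=i, j=j), k_form))
    for site in lattice.iter_sites(flare_mode=params.flare_mode):
        if site.occupied:
            k = eb1_off_rate(site.structural_class, site.nucleotide_class, params)
            if k > 0:
                out.append(
                    (Event(EventKind.EB1_OFF, interface=site.interface, j=site.j), k)
                )
        else:
            k = eb1_on_rate(site.structural_class, params)
            if k > 0:
                out.append(
                    (Event(EventKind.EB1_ON, interface=site.interface, j=site.j), k)
                )
    return out


def step(
    lattice: Lattice,
    params: KineticParameters,
    rng: np.random.Generator,
    boosted: bool = False,
) -> StepResult:
    """Execute exactly one first-reaction event plus the hydrolysis sub-step."""
    candidates = enumerate_candidates(lattice, params, boosted)
    if not candidates:
        raise RuntimeError("no feasible event (unreachable with arrivals enabled)")
    times = [draw_event_time(k, rng) for _, k in candidates]
    winner = int(np.argmin(times))
    event, _ = candidates[winner]
    dt = times[winner]
    forced = lattice.apply_event(event)

    hydrolyzed = None
    gtp_positions = [
        (p, j)
        for p in range(lattice.n_pf)
        for j in range(lattice.seed_length, int(lattice.length[p]))
        if not lattice.gdp[p, j]
    ]
    if gtp_positions and params.k_hydrolysis > 0:
        t_hyd = draw_event_time(params.k_hydrolysis * len(gtp_positions), rng)
        if t_hyd < dt:
            p, j = gtp_positions[int(rng.integers(len(gtp_positions)))]
            lattice.apply_event(Event(EventKind.HYDROLYSIS, pf=p, j=j))
            hydrolyzed = (p, j)
    return StepResult(event=event, dt=dt, hydrolyzed=hydrolyzed, forced_releases=forced)


def run_occupancy(
    lattice: Lattice,
    params: KineticParameters,
    rng: np.random.Generator,
    n_steps: int,
) -> tuple[float, dict]:
    """Time-averaged EB1 occupancy (and per-site dwell) on a frozen lattice.

    Intended for EB1-only configurations (all tubulin and bond rates zero),
    where the closed-form equilibrium per site is
    ``k_on [EB1] / (k_on [EB1] + k_off)``.
    """
    total_time = 0.0
    occupied_time = 0.0
    site_time: dict[tuple[int, int], float] = {}
    for _ in range(n_steps):
        # the pre-event state persists for the step's dwell time dt
        top = int(lattice.length.max())
        bound_before = [
            (i, int(j))
            for i in range(lattice.n_pf)
            for j in np.nonzero(lattice.occ[i, :top])[0]
        ]
        res = step(lattice, params, rng)
        total_time += res.dt
        occupied_time += len(bound_before) * res.dt
        for key in bound_before:
            site_time[key] = site_time.get(key, 0.0) + res.dt
    mean_occ = occupied_time / total_time if total_time else 0.0
    site_frac = {k: v / total_time for k, v in site_time.items()}
    return mean_occ, site_frac
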