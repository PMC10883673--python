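"""Stochastic first-reaction simulation loop, trajectory container and census.

A run advances one event at a time: all candidate event times are
exponential with their single-molecule rates, the shortest executes, then a
single hydrolysis time is drawn from the aggregate GTP-hydrolysis rate
(``k_hydrolysis`` x number of non-seed GTP dimers) and, if shorter than the
executed event's time, one uniformly random non-seed GTP dimer converts to
GDP.  After every event the taper rule is evaluated: when the difference
between the longest and the second-shortest protofilament exceeds the taper
threshold (600 nm = 75 dimers at baseline), tubulin off-rates and the
lateral-bond breakage rate are multiplied by ``catastrophe_boost``, which
rapidly shortens the microtubule until the taper falls back below the
threshold (implicit rescue).

Every ``record_interval`` steps (default 1000, typically 0.5-2 s of
simulated time) the protofilament lengths, every bound EB1 position with its
class at binding, the non-seed GTP map and the cumulative event tallies are
stored in a :class:`Trajectory`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import h5py
import numpy as np
import pandas as pd

from . import _kernel as K
from .kinetics import KineticParameters, NUCLEOTIDES
from .lattice import DIMER_LENGTH_NM, ConfigurationError, Lattice

#: parameter names that a rate-switch schedule may target
SWITCHABLE_PARAMS = {
    "tubulin_conc": K.P_TUB_CONC,
    "k_on_tubulin": K.P_K_ON_TUB,
    "k_hydrolysis": K.P_K_HYD,
    "k_lat_form": K.P_K_FORM,
    "k_lat_break_base": K.P_K_BREAK_BASE,
    "pi_break": K.P_PI_BREAK,
    "max_taper_dimers": K.P_MAX_TAPER,
    "eb1_conc": K.P_EB1_CONC,
    "k_on_edge": K.P_K_ON_EDGE,
    "k_on_closed": K.P_K_ON_CLOSED,
    "k_off_closed_GTP": K.P_KOFF_CG,
    "k_off_closed_GDP": K.P_KOFF_CD,
    "k_off_edge_GTP": K.P_KOFF_EG,
    "k_off_edge_GDP": K.P_KOFF_ED,
}

STATUS_NAMES = {
    K.STATUS_STEPS: "max_steps",
    K.STATUS_TIME: "max_time",
    K.STATUS_CAPACITY: "capacity",
    K.STATUS_CATASTROPHE: "catastrophe",
    K.STATUS_STORE_FULL: "store_full",
}

TALLY_NAMES = [
    "tubulin_on",
    "tubulin_off",
    "lat_form",
    "lat_break",
    "eb1_on_edge",
    "eb1_on_closed",
    "eb1_off",
    "forced_release",
    "hydrolysis",
]

BOUND_CLASS_NAMES = ["closed_GTP", "closed_GDP", "edge_GTP", "edge_GDP"]


def pack_params(params: KineticParameters) -> np.ndarray:
    P = np.zeros(K.N_PARAMS, dtype=np.float64)
    P[K.P_TUB_CONC] = params.tubulin_conc
    P[K.P_K_ON_TUB] = params.k_on_tubulin
    tab = params.k_off_tubulin_base
    P[K.P_OFF_GTP0] = tab[("GTP", 0)]
    P[K.P_OFF_GTP1] = tab[("GTP", 1)]
    P[K.P_OFF_GTP2] = tab[("GTP", 2)]
    P[K.P_OFF_GDP0] = tab[("GDP", 0)]
    P[K.P_OFF_GDP1] = tab[("GDP", 1)]
    P[K.P_OFF_GDP2] = tab[("GDP", 2)]
    P[K.P_K_HYD] = params.k_hydrolysis
    P[K.P_K_FORM] = params.k_lat_form
    P[K.P_K_BREAK_BASE] = params.k_lat_break_base
    P[K.P_PI_BREAK] = params.pi_break
    P[K.P_BOOST] = params.catastrophe_boost
    P[K.P_MAX_TAPER] = params.max_taper_dimers
    P[K.P_EB1_CONC] = params.eb1_conc
    P[K.P_K_ON_EDGE] = params.k_on_edge
    P[K.P_K_ON_CLOSED] = params.k_on_closed
    P[K.P_KOFF_CG] = params.k_off_closed_GTP
    P[K.P_KOFF_CD] = params.k_off_closed_GDP
    P[K.P_KOFF_EG] = params.k_off_edge_GTP
    P[K.P_KOFF_ED] = params.k_off_edge_GDP
    P[K.P_MONOMER] = 1.0 if params.monomer_mode else 0.0
    P[K.P_FLARE] = 1.0 if params.flare_mode else 0.0
    return P


@dataclass
class SimulationConfig:
    """Run settings for one stochastic trajectory."""

    params: KineticParameters = field(default_factory=KineticParameters)
    n_steps: int = 200_000
    record_interval: int = 1000
    rng_seed: int = 0
    n_pf: int = 13
    seed_length: int = 25
    capacity: int = 4096
    max_sim_time: float = 1e9  # s
    rate_switch_schedule: list = field(default_factory=list)  # [(t, name, value)]
    #: stop at the first catastrophe once the mean protofilament length (in
    #: dimers) reaches this value; 0 disables early stopping
    stop_after_catastrophe_dimers: int = 0
    #: storage reserved per snapshot for bound-EB1 positions (split-comet
    #: runs at high tubulin concentration carry thousands of bound EB1s)
    bound_store_per_snapshot: int = 4096

    def __post_init__(self) -> None:
        if self.record_interval < 1:
            raise ConfigurationError("record_interval must be >= 1")
        times = [t for t, _, _ in self.rate_switch_schedule]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ConfigurationError("rate switch schedule times must be nondecreasing")
        for _, name, _ in self.rate_switch_schedule:
            if name not in SWITCHABLE_PARAMS:
                raise ConfigurationError(
                    f"unknown switch target {name!r}; valid: {sorted(SWITCHABLE_PARAMS)}"
                )


@dataclass
class Trajectory:
    """Recorded output of one run: snapshots, tallies and catastrophes."""

    config: SimulationConfig
    times: np.ndarray  # (n_snap,) s
    lengths: np.ndarray  # (n_snap, n_pf) dimers
    bound_counts: np.ndarray  # (n_snap, 4): closed_GTP, closed_GDP, edge_GTP, edge_GDP
    tallies: np.ndarray  # (n_snap, 9) cumulative event counts
    bound_i: np.ndarray  # flat bound-EB1 interface indices
    bound_j: np.ndarray  # flat bound-EB1 pocket heights
    bound_origin: np.ndarray  # flat class-at-binding (1 edge, 2 closed)
    bound_offsets: np.ndarray  # (n_snap + 1,)
    gtp_p: np.ndarray  # flat non-seed GTP dimer protofilaments
    gtp_j: np.ndarray  # flat non-seed GTP dimer heights
    gtp_offsets: np.ndarray  # (n_snap + 1,)
    boost_times: np.ndarray  # taper-rule transitions, s
    boost_flags: np.ndarray  # 1 = boost on (catastrophe), 0 = off (rescue)
    status: str
    end_time: float
    final_state: dict

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def snapshot(self, idx: int) -> dict:
        """One stored snapshot: time, pf lengths, bound EB1s, GTP map."""
        a, b = self.bound_offsets[idx], self.bound_offsets[idx + 1]
        g, h = self.gtp_offsets[idx], self.gtp_offsets[idx + 1]
        return {
            "time": float(self.times[idx]),
            "lengths": self.lengths[idx].copy(),
            "eb1_interface": self.bound_i[a:b].copy(),
            "eb1_j": self.bound_j[a:b].copy(),
            "eb1_origin": self.bound_origin[a:b].copy(),
            "gtp_p": self.gtp_p[g:h].copy(),
            "gtp_j": self.gtp_j[g:h].copy(),
        }

    # ------------------------------------------------------------------ #

    def mean_length_nm(self) -> np.ndarray:
        """Mean protofilament length per snapshot, nm."""
        return self.lengths.mean(axis=1) * DIMER_LENGTH_NM

    def catastrophe_times(self, min_growth_nm: float = 1000.0) -> np.ndarray:
        """Times of taper-rule trips after >= ``min_growth_nm`` of net growth."""
        out = []
        seed_nm = self.config.seed_length * DIMER_LENGTH_NM
        mean_nm = self.mean_length_nm()
        for t, f in zip(self.boost_times, self.boost_flags):
            if not f:
                continue
            idx = np.searchsorted(self.times, t) - 1
            grown = mean_nm[idx] if idx >= 0 else 0.0
            if grown - seed_nm >= min_growth_nm:
                out.append(float(t))
        return np.asarray(out)

    def tallies_dict(self, idx: int = -1) -> dict:
        return dict(zip(TALLY_NAMES, (int(v) for v in self.tallies[idx])))

    def snapshots_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.lengths, columns=[f"pf{p}" for p in range(self.lengths.shape[1])])
        df.insert(0, "time_s", self.times)
        for c, name in enumerate(BOUND_CLASS_NAMES):
            df[f"bound_{name}"] = self.bound_counts[:, c]
        return df

    # ------------------------------------------------------------------ #
    # persistence (single hierarchical file per run)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in (
                "times lengths bound_counts tallies bound_i bound_j bound_origin "
                "bound_offsets gtp_p gtp_j gtp_offsets boost_times boost_flags"
            ).split():
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["status"] = self.status
            f.attrs["end_time"] = self.end_time
            cfg = self.config
            for name in ("n_steps", "record_interval", "rng_seed", "n_pf",
                         "seed_length", "capacity", "max_sim_time",
                         "stop_after_catastrophe_dimers"):
                f.attrs[f"config/{name}"] = getattr(cfg, name)
            p = cfg.params
            for fld in dc_fields(p):
                v = getattr(p, fld.name)
                if fld.name == "k_off_tubulin_base":
                    v = [v[(nuc, b)] for nuc in NUCLEOTIDES for b in range(3)]
                f.attrs[f"params/{fld.name}"] = v
            if cfg.rate_switch_schedule:
                f.attrs["schedule/times"] = [t for t, _, _ in cfg.rate_switch_schedule]
                f.attrs["schedule/names"] = [n for _, n, _ in cfg.rate_switch_schedule]
                f.attrs["schedule/values"] = [v for _, _, v in cfg.rate_switch_schedule]

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        with h5py.File(path, "r") as f:
            arrays = {
                name: f[name][...]
                for name in (
                    "times lengths bound_counts tallies bound_i bound_j bound_origin "
                    "bound_offsets gtp_p gtp_j gtp_offsets boost_times boost_flags"
                ).split()
            }
            pkw = {}
            for key, v in f.attrs.items():
                if key.startswith("params/"):
                    name = key.split("/", 1)[1]
                    if name == "k_off_tubulin_base":
                        v = {
                            (nuc, b): float(v[k * 3 + b])
                            for k, nuc in enumerate(NUCLEOTIDES)
                            for b in range(3)
                        }
                    elif name in ("monomer_mode", "flare_mode"):
                        v = bool(v)
                    pkw[name] = v
            params = KineticParameters(**pkw)
            schedule = []
            if "schedule/times" in f.attrs:
                schedule = list(
                    zip(
                        (float(t) for t in f.attrs["schedule/times"]),
                        (str(n) for n in f.attrs["schedule/names"]),
                        (float(v) for v in f.attrs["schedule/values"]),
                    )
                )
            cfg = SimulationConfig(
                params=params,
                rate_switch_schedule=schedule,
                **{
                    name: int(f.attrs[f"config/{name}"])
                    if name != "max_sim_time"
                    else float(f.attrs[f"config/{name}"])
                    for name in (
                        "n_steps", "record_interval", "rng_seed", "n_pf",
                        "seed_length", "capacity", "max_sim_time",
                        "stop_after_catastrophe_dimers",
                    )
                },
            )
            return cls(
                config=cfg,
                status=str(f.attrs["status"]),
                end_time=float(f.attrs["end_time"]),
                final_state={},
                **arrays,
            )


def apply_catastrophe_rule(lattice_lengths: np.ndarray, params: KineticParameters) -> bool:
    """Boost flag: taper (longest minus second-shortest pf) above threshold."""
    srt = np.sort(np.asarray(lattice_lengths))
    taper_nm = float(srt[-1] - srt[1]) * DIMER_LENGTH_NM
    return taper_nm > params.max_taper_dimers * DIMER_LENGTH_NM


def run(config: SimulationConfig) -> Trajectory:
    """Run one seeded stochastic trajectory.

    Deterministic given ``config.rng_seed``: one generator drives the whole
    run and the stream order is part of the reproducibility contract.
    """
    params = config.params
    for _, name, _ in config.rate_switch_schedule:
        if name not in SWITCHABLE_PARAMS:
            raise ConfigurationError(f"unknown switch target {name!r}")
    P = pack_params(params)
    n_pf, seed_len, cap = config.n_pf, config.seed_length, config.capacity

    lat = Lattice(n_pf=n_pf, seed_length=seed_len, capacity=cap)
    length = lat.length
    gdp, bond, occ, origin = lat.gdp, lat.bond, lat.occ, lat.origin
    site_state = np.zeros((n_pf, cap), dtype=np.uint8)

    n_snap_max = config.n_steps // config.record_interval + 2
    snap_time = np.zeros(n_snap_max, dtype=np.float64)
    snap_len = np.zeros((n_snap_max, n_pf), dtype=np.int64)
    snap_counts = np.zeros((n_snap_max, 4), dtype=np.int64)
    snap_tallies = np.zeros((n_snap_max, K.N_TALLIES), dtype=np.int64)
    occ_store = n_snap_max * config.bound_store_per_snapshot
    occ_store_i = np.zeros(occ_store, dtype=np.int32)
    occ_store_j = np.zeros(occ_store, dtype=np.int32)
    occ_store_orig = np.zeros(occ_store, dtype=np.int32)
    occ_offsets = np.zeros(n_snap_max + 1, dtype=np.int64)
    gtp_store = n_snap_max * 4096
    gtp_store_p = np.zeros(gtp_store, dtype=np.int32)
    gtp_store_j = np.zeros(gtp_store, dtype=np.int32)
    gtp_offsets = np.zeros(n_snap_max + 1, dtype=np.int64)
    boost_times = np.zeros(4096, dtype=np.float64)
    boost_flags = np.zeros(4096, dtype=np.int64)

    sched = sorted(config.rate_switch_schedule, key=lambda s: s[0])
    sw_time = np.array([t for t, _, _ in sched], dtype=np.float64)
    sw_slot = np.array([SWITCHABLE_PARAMS[n] for _, n, _ in sched], dtype=np.int64)
    sw_value = np.array([v for _, _, v in sched], dtype=np.float64)

    status, n_snap, n_boost, end_time, final_tallies = K.run_kernel(
        int(config.rng_seed) % (2**31),
        int(config.n_steps),
        float(config.max_sim_time),
        int(config.record_interval),
        seed_len,
        P,
        sw_time,
        sw_slot,
        sw_value,
        int(config.stop_after_catastrophe_dimers),
        length, gdp, bond, occ, origin, site_state,
        snap_time, snap_len, snap_counts, snap_tallies,
        occ_store_i, occ_store_j, occ_store_orig, occ_offsets,
        gtp_store_p, gtp_store_j, gtp_offsets,
        boost_times, boost_flags,
    )

    n_bound_flat = int(occ_offsets[n_snap])
    n_gtp_flat = int(gtp_offsets[n_snap])
    return Trajectory(
        config=config,
        times=snap_time[:n_snap].copy(),
        lengths=snap_len[:n_snap].copy(),
        bound_counts=snap_counts[:n_snap].copy(),
        tallies=snap_tallies[:n_snap].copy(),
        bound_i=occ_store_i[:n_bound_flat].copy(),
        bound_j=occ_store_j[:n_bound_flat].copy(),
        bound_origin=occ_store_orig[:n_bound_flat].copy(),
        bound_offsets=occ_offsets[: n_snap + 1].copy(),
        gtp_p=gtp_store_p[:n_gtp_flat].copy(),
        gtp_j=gtp_store_j[:n_gtp_flat].copy(),
        gtp_offsets=gtp_offsets[: n_snap + 1].copy(),
        boost_times=boost_times[:n_boost].copy(),
        boost_flags=boost_flags[:n_boost].copy(),
        status=STATUS_NAMES[int(status)],
        end_time=float(end_time),
        final_state={
            "length": length,
            "gdp": gdp,
            "bond": bond,
            "occ": occ,
            "origin": origin,
            "site_state": site_state,
            "tallies": final_tallies,
        },
    )


def census(trajectory: Trajectory, at_time: float | None = None) -> dict:
    """Bound-EB1 counts by pocket class and binding-event fractions by origin.

    Counts are taken at the last snapshot at or before ``at_time`` (default:
    final snapshot); binding-event fractions are cumulative up to that
    snapshot.  Returns an empty dict for an empty trajectory.
    """
    if trajectory.n_snapshots == 0:
        return {}
    if at_time is None:
        idx = trajectory.n_snapshots - 1
    else:
        idx = int(np.searchsorted(trajectory.times, at_time, side="right")) - 1
        idx = max(idx, 0)
    counts = dict(zip(BOUND_CLASS_NAMES, (int(v) for v in trajectory.bound_counts[idx])))
    tal = trajectory.tallies_dict(idx)
    n_edge = tal["eb1_on_edge"]
    n_closed = tal["eb1_on_closed"]
    total = n_edge + n_closed
    return {
        "bound_counts": counts,
        "edge_binding_fraction": n_edge / total if total else float("nan"),
        "closed_binding_fraction": n_closed / total if total else float("nan"),
        "n_binding_events": total,
        "time": float(trajectory.times[idx]),
    }


def mean_bound_counts(trajectory: Trajectory, t_min: float = 0.0) -> dict:
    """Time-averaged bound-EB1 counts by class over snapshots with t >= t_min."""
    sel = trajectory.times >= t_min
    if not sel.any():
        return {}
    means = trajectory.bound_counts[sel].mean(axis=0)
    return dict(zip(BOUND_CLASS_NAMES, (float(v) for v in means)))
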