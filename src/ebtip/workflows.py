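"""Named experiment presets, growth-event ensembles and the sweep harness.

A *preset* is pure data: a name, parameter overrides relative to baseline,
and run settings.  A *growth event* is one seeded run growing from the seed
until its first catastrophe (or a time cap); events whose lattice was
scarred by an earlier catastrophe/rescue before reaching the analysis
length are discarded, because regrown stretches carry fresh GTP-tubulin and
would contaminate lattice-intensity measurements.

The ensemble pipeline reproduces the imaging-based quantification chain:
model-convolve one frame per event, take line scans, register at the EB1
peak, average at least five events, and measure peak EB1 position,
tip:lattice ratio and tip standard deviation; Tip Specificity is measured
per event on a short time-average of frames aligned at the comet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import analysis as an
from .engine import SimulationConfig, Trajectory, run
from .imaging import Image, RenderSettings, draw_labels, render_frame
from .kinetics import KineticParameters
from .lattice import DIMER_LENGTH_NM


@dataclass(frozen=True)
class Preset:
    """A named experiment: parameter overrides plus run settings."""

    name: str
    overrides: dict = field(default_factory=dict)
    replicate_count: int = 10
    n_steps: int = 500_000
    max_sim_time: float = 400.0
    description: str = ""


PRESETS: dict[str, Preset] = {
    p.name: p
    for p in [
        Preset("baseline", {}, description="baseline kinetic parameter set"),
        Preset(
            "slow_hydrolysis",
            {"k_hydrolysis": 0.05},
            description="slow GTP hydrolysis (0.05 vs 0.55 s^-1)",
        ),
        Preset(
            "monomer",
            {"monomer_mode": True},
            description="EB1 monomers: all EB1 off-rates x4",
        ),
        Preset("flared", {"flare_mode": True},
               description="flared tip: edge class distal of last lateral bond"),
        Preset("no_edge_binding", {"k_on_edge": 0.0},
               description="EB1 protofilament-edge on-rate set to zero"),
        Preset("no_closed_binding", {"k_on_closed": 0.0},
               description="EB1 closed-lattice on-rate set to zero"),
        Preset(
            "rate_switch",
            {},
            description="edge on-rate switched to zero mid-run and restored",
        ),
        Preset(
            "split_comet",
            {"tubulin_conc": 30.0, "pi_break": 6.0, "max_taper_dimers": 400},
            n_steps=900_000,
            max_sim_time=200.0,
            description="split comets: 30 uM tubulin, pi_break 6, taper cap ~400 dimers",
        ),
    ]
}

#: schedule used by the rate_switch preset: edge binding off, then restored
RATE_SWITCH_SCHEDULE = [(60.0, "k_on_edge", 0.0), (90.0, "k_on_edge", 4.7e-3)]


def get_preset(name: str) -> Preset:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name]


def preset_params(name: str, base: KineticParameters | None = None) -> KineticParameters:
    base = base or KineticParameters()
    return base.with_overrides(**get_preset(name).overrides)


# --------------------------------------------------------------------- #
# growth events


@dataclass
class GrowthEvent:
    """One clean growth event with its analysis snapshot index."""

    trajectory: Trajectory
    snapshot_index: int
    seed: int


def collect_growth_events(
    params: KineticParameters,
    n_events: int,
    base_seed: int = 0,
    min_length_dimers: int = 235,
    n_steps: int = 500_000,
    max_sim_time: float = 400.0,
    max_attempts: int | None = None,
    require_clean: bool = True,
) -> list[GrowthEvent]:
    """Run seeded simulations until ``n_events`` clean growth events exist.

    The analysis snapshot is the first at which every protofilament exceeds
    ``min_length_dimers`` (enough lattice for a 1024 nm window well clear of
    the seed).  Events with any taper-rule trip before that point are
    discarded when ``require_clean``.  Replicate seeds are
    ``base_seed + 1, base_seed + 2, ...``.
    """
    if max_attempts is None:
        max_attempts = 8 * n_events
    events = []
    seed = base_seed
    attempts = 0
    while len(events) < n_events and attempts < max_attempts:
        seed += 1
        attempts += 1
        traj = run(
            SimulationConfig(
                params=params,
                n_steps=n_steps,
                rng_seed=seed,
                max_sim_time=max_sim_time,
                stop_after_catastrophe_dimers=60,
            )
        )
        ok = np.nonzero(traj.lengths.min(axis=1) >= min_length_dimers)[0]
        if ok.size == 0:
            continue
        idx = int(ok[0])
        if require_clean and len(traj.boost_times) and traj.boost_times[0] < traj.times[idx]:
            continue
        events.append(GrowthEvent(trajectory=traj, snapshot_index=idx, seed=seed))
    if len(events) < n_events:
        warnings.warn(
            f"collected only {len(events)}/{n_events} clean growth events",
            stacklevel=2,
        )
    return events


def event_profile(
    event: GrowthEvent, settings: RenderSettings, rng_salt: int = 9000
) -> an.LineScanProfile:
    """Model-convolve the event's analysis snapshot and take its line scan."""
    rng = np.random.default_rng(rng_salt + event.seed)
    img = render_frame(event.trajectory.snapshot(event.snapshot_index), settings, rng)
    return an.line_scan(img)


def ensemble_averaged_profile(
    events: list[GrowthEvent], settings: RenderSettings | None = None
) -> an.LineScanProfile:
    settings = settings or RenderSettings()
    return an.register_and_average([event_profile(e, settings) for e in events])


def steady_growth_census(event: GrowthEvent, start_length_nm: float = 1000.0) -> dict:
    """Binding-origin census over the event's steady-growth window.

    Tallies are differenced between the snapshot where the mean length first
    reaches ``start_length_nm`` and the end of the run, excluding the seed
    equilibration and short-lattice transient.
    """
    traj = event.trajectory
    mean_nm = traj.mean_length_nm()
    j0 = int(np.searchsorted(mean_nm, start_length_nm))
    j0 = min(j0, traj.n_snapshots - 1)
    d = traj.tallies[-1] - traj.tallies[j0]
    n_edge, n_closed = int(d[4]), int(d[5])
    total = n_edge + n_closed
    return {
        "edge_binding_fraction": n_edge / total if total else float("nan"),
        "n_binding_events": total,
    }


def mean_bound_by_class(event: GrowthEvent) -> dict:
    """Time-averaged bound-EB1 counts by class over the event's second half."""
    traj = event.trajectory
    t_min = traj.times[event.snapshot_index] * 0.5
    sel = traj.times >= t_min
    means = traj.bound_counts[sel].mean(axis=0)
    return dict(zip(["closed_GTP", "closed_GDP", "edge_GTP", "edge_GDP"], means))


# --------------------------------------------------------------------- #
# Tip Specificity per event (short time-average of aligned frames)


def _comet_column(img: Image) -> int:
    prof = an.line_scan(img)
    half = 0.5 * (prof.red.max() + prof.red.min())
    above = np.nonzero(prof.red >= half)[0]
    if above.size == 0:
        raise an.AnalysisError("no microtubule end in frame")
    end = int(above[-1])
    w = int(round(512.0 / img.pixel_size_nm))
    lo = max(0, end - w)
    hi = min(prof.green.size, end + w + 1)
    return lo + int(np.argmax(prof.green[lo:hi]))


def event_tip_specificity(
    event: GrowthEvent,
    settings: RenderSettings | None = None,
    n_frames: int = 5,
    rng_salt: int = 8000,
) -> float:
    """Tip Specificity S for one growth event.

    The last ``n_frames`` snapshots up to the analysis frame are rendered
    with the event's persistent label mask, aligned at the comet peak
    column, and averaged; S is then measured from 4x4-pixel boxes on the
    averaged frame (tip at the brightest green pixel near the end, lattice
    1 um behind, background transversely offset).
    """
    settings = settings or RenderSettings()
    traj = event.trajectory
    idx = event.snapshot_index
    labels = draw_labels(
        traj.lengths.shape[1], traj.config.capacity, settings.label_fraction,
        np.random.default_rng(7000 + event.seed),
    )
    rng = np.random.default_rng(rng_salt + event.seed)
    width = float(traj.lengths.max()) * DIMER_LENGTH_NM + 2 * settings.margin_nm
    frames = [
        render_frame(traj.snapshot(k), settings, rng, labels=labels, width_nm=width)
        for k in range(max(0, idx - n_frames + 1), idx + 1)
    ]
    cols = [_comet_column(f) for f in frames]
    c0 = cols[-1]
    green = np.mean([np.roll(f.green, c0 - c, axis=1) for f, c in zip(frames, cols)], axis=0)
    red = np.mean([np.roll(f.red, c0 - c, axis=1) for f, c in zip(frames, cols)], axis=0)
    avg = Image(red=red, green=green, pixel_size_nm=settings.pixel_size_nm,
                origin_nm=frames[0].origin_nm)
    return an.tip_specificity(avg, background_offset_px=9).s


# --------------------------------------------------------------------- #
# ensemble measurement table


def measure_ensemble(
    params: KineticParameters,
    n_events: int = 10,
    base_seed: int = 0,
    settings: RenderSettings | None = None,
    min_length_dimers: int = 235,
    n_steps: int = 500_000,
    max_sim_time: float = 400.0,
) -> dict:
    """Full quantification of one condition: per-event and ensemble metrics."""
    settings = settings or RenderSettings()
    events = collect_growth_events(
        params, n_events, base_seed=base_seed, min_length_dimers=min_length_dimers,
        n_steps=n_steps, max_sim_time=max_sim_time,
    )
    profiles = [event_profile(e, settings) for e in events]
    avg = an.register_and_average(profiles)
    per_event = []
    for e, prof in zip(events, profiles):
        row = {"seed": e.seed}
        row.update(an.growth_stats(e.trajectory))
        try:
            row["sigma_tip_nm"] = an.tip_standard_deviation(prof).sigma_tip
        except an.FitError:
            row["sigma_tip_nm"] = np.nan
        try:
            row["tip_specificity"] = event_tip_specificity(e, settings)
        except an.AnalysisError:
            row["tip_specificity"] = np.nan
        row.update(steady_growth_census(e))
        per_event.append(row)
    table = pd.DataFrame(per_event)
    tip = float(avg.green[np.abs(avg.positions) <= 512].max())
    lat_sel = (avg.positions >= 768) & (avg.positions <= 1024)
    lattice = float(np.median(avg.green[lat_sel]))
    return {
        "events": events,
        "profiles": profiles,
        "averaged_profile": avg,
        "per_event": table,
        "peak_eb1_position_nm": an.peak_eb1_position(avg),
        "tip_intensity": tip,
        "lattice_intensity": lattice,
        "tip_lattice_ratio": an.tip_lattice_ratio(avg),
        "mean_sigma_tip_nm": float(table["sigma_tip_nm"].mean()),
        "sem_sigma_tip_nm": float(table["sigma_tip_nm"].sem()),
        "mean_tip_specificity": float(table["tip_specificity"].mean()),
        "mean_growth_rate_nm_s": float(table["growth_rate_nm_s"].mean()),
        "mean_edge_binding_fraction": float(table["edge_binding_fraction"].mean()),
    }


def run_preset(
    name: str,
    n_replicates: int | None = None,
    base_seed: int = 0,
    settings: RenderSettings | None = None,
) -> dict:
    """Run a named preset and return its ensemble measurement tables.

    Replicate seeds are ``base_seed + replicate index``.  The result
    contains the per-replicate table, the aggregate metrics and the fully
    resolved parameter set (config echo).
    """
    preset = get_preset(name)
    params = preset_params(name)
    n = n_replicates or preset.replicate_count
    if name == "split_comet":
        res = split_comet_experiment(params, n_events=n, base_seed=base_seed,
                                     settings=settings)
    elif name == "rate_switch":
        res = {"trajectories": [
            run(SimulationConfig(params=params, n_steps=preset.n_steps,
                                 rng_seed=base_seed + i + 1,
                                 max_sim_time=preset.max_sim_time,
                                 rate_switch_schedule=RATE_SWITCH_SCHEDULE))
            for i in range(n)
        ]}
    else:
        res = measure_ensemble(params, n_events=n, base_seed=base_seed,
                               settings=settings, n_steps=preset.n_steps,
                               max_sim_time=preset.max_sim_time)
    res["preset"] = preset
    res["params"] = params
    return res


# --------------------------------------------------------------------- #
# split comets


def _split_frame_info(
    img: Image,
    seed_top_nm: float,
    min_separation_nm: float = 720.0,
    prominence_factor: float = 0.10,
    window_behind_nm: float = 3200.0,
    window_ahead_nm: float = 1600.0,
):
    """Comet count/extent near the growing end, excluding the seed region."""
    prof = an.line_scan(img)
    half = 0.5 * (prof.red.max() + prof.red.min())
    above = np.nonzero(prof.red >= half)[0]
    if above.size == 0:
        return None
    end = int(above[-1])
    dx = prof.spacing
    min_col = int(np.searchsorted(prof.positions, seed_top_nm + 500.0))
    lo = max(min_col, end - int(window_behind_nm / dx))
    hi = min(prof.green.size, end + int(window_ahead_nm / dx))
    if hi - lo < 10:
        return None
    g = prof.green[lo:hi]
    bg = float(np.percentile(prof.green, 10))
    contrast = float(g.max() - bg)
    if contrast <= 0:
        return None
    peaks, _ = find_peaks(
        g, distance=max(1, int(min_separation_nm / dx)),
        prominence=prominence_factor * contrast,
    )
    if peaks.size == 0:
        return None
    thr = bg + 0.08 * contrast
    ext_lo, ext_hi = np.inf, -np.inf
    for k in peaks:
        a = k
        while a > 0 and g[a] > thr:
            a -= 1
        b = k
        while b < len(g) - 1 and g[b] > thr:
            b += 1
        ext_lo = min(ext_lo, a + lo)
        ext_hi = max(ext_hi, b + lo)
    return {
        "n_comets": int(peaks.size),
        "brightness": float(g[peaks].max()),
        "lo": int(ext_lo),
        "hi": int(ext_hi),
        "time": img.time_s,
    }


def split_comet_experiment(
    params: KineticParameters | None = None,
    n_events: int = 10,
    base_seed: int = 0,
    settings: RenderSettings | None = None,
    n_steps: int = 900_000,
    max_sim_time: float = 200.0,
    pair_window_s: float = 40.0,
) -> dict:
    """Paired single- vs split-comet summed intensities on common regions.

    For each growth event that exhibits a comet split, the brightest
    split-comet frame is paired with the brightest preceding single-comet
    frame within ``pair_window_s``; green intensity is summed over the
    smallest region encapsulating all comets in both frames, a seed-only
    background frame is subtracted from both, and the paired fold change is
    reported.  Events without a split (or without a preceding single frame)
    are skipped, mirroring the original protocol.
    """
    params = params or preset_params("split_comet")
    settings = settings or RenderSettings()
    rows = []
    seed = base_seed
    attempts = 0
    while len(rows) < n_events and attempts < 4 * n_events:
        seed += 1
        attempts += 1
        traj = run(
            SimulationConfig(
                params=params, n_steps=n_steps, rng_seed=seed,
                max_sim_time=max_sim_time, stop_after_catastrophe_dimers=100,
                capacity=4096,
            )
        )
        labels = draw_labels(traj.lengths.shape[1], traj.config.capacity,
                             settings.label_fraction, np.random.default_rng(7000 + seed))
        rng = np.random.default_rng(8000 + seed)
        width = float(traj.lengths.max()) * DIMER_LENGTH_NM + 2 * settings.margin_nm
        seed_top_nm = traj.config.seed_length * DIMER_LENGTH_NM
        frames = []
        for k in range(traj.n_snapshots):
            if traj.lengths[k].min() < 60:
                continue
            img = render_frame(traj.snapshot(k), settings, rng, labels=labels,
                               width_nm=width)
            info = _split_frame_info(img, seed_top_nm)
            if info:
                frames.append((info, img))
        splits = [(i, im) for i, im in frames if i["n_comets"] >= 2]
        if not splits:
            continue
        isplit, im_split = max(splits, key=lambda x: x[0]["brightness"])
        singles = [
            (i, im) for i, im in frames
            if i["n_comets"] == 1 and 0 < isplit["time"] - i["time"] < pair_window_s
        ]
        if not singles:
            continue
        ising, im_single = max(singles, key=lambda x: x[0]["brightness"])
        lo = max(0, min(isplit["lo"], ising["lo"]) - 4)
        hi = min(im_split.green.shape[1] - 1, max(isplit["hi"], ising["hi"]) + 4)
        background = render_frame(
            {"lengths": np.full(traj.lengths.shape[1], traj.config.seed_length),
             "eb1_j": np.zeros(0), "time": 0.0},
            settings, np.random.default_rng(99000 + seed), labels=labels,
            width_nm=width,
        )
        pair = an.split_comet_fold_change(im_single, im_split, background,
                                          region=(lo, hi))
        rows.append({
            "seed": seed,
            "t_single_s": ising["time"],
            "t_split_s": isplit["time"],
            "fold_change": pair.fold_change,
            "summed_single": pair.summed_single,
            "summed_split": pair.summed_split,
            "summed_background": pair.summed_background,
        })
    table = pd.DataFrame(rows)
    mean_fold = float(table["fold_change"].mean()) if len(table) else float("nan")
    return {
        "per_event": table,
        "mean_fold_change": mean_fold,
        "percent_increase": 100.0 * (mean_fold - 1.0),
        "n_split_events": len(table),
    }


# --------------------------------------------------------------------- #
# parameter sweeps


DEFAULT_MULTIPLIERS = tuple(2.0**k for k in range(-4, 5))  # 1/16 .. 16


def sweep(
    parameter_name: str,
    multipliers=DEFAULT_MULTIPLIERS,
    reference_profile: an.LineScanProfile | None = None,
    n_replicates: int = 10,
    base_seed: int = 0,
    settings: RenderSettings | None = None,
    n_events_per_point: int | None = None,
    params: KineticParameters | None = None,
    score_window_nm: tuple[float, float] = (-512.0, 1536.0),
) -> pd.DataFrame:
    """Vary one parameter over fold-multipliers of baseline; score each point.

    Per multiplier: ``n_replicates`` growth events, an averaged line-scan
    profile, tip (peak green near the end) and lattice (median green
    768-1024 nm behind the end) intensities, tip:lattice ratio, and — when a
    reference profile is given — the sum of absolute errors against it.
    Error scoring registers each replicate profile into end-relative
    coordinates and restricts it to ``score_window_nm`` around the comet, so
    the score reflects comet shape rather than far-lattice noise.
    """
    base = params or KineticParameters()
    if not hasattr(base, parameter_name):
        raise KeyError(f"unknown parameter {parameter_name!r}")
    base_value = getattr(base, parameter_name)
    settings = settings or RenderSettings()
    n_ev = n_events_per_point or n_replicates
    out = []
    for im, mult in enumerate(multipliers):
        p = base.with_overrides(**{parameter_name: base_value * mult})
        events = collect_growth_events(p, n_ev, base_seed=base_seed + 1000 * im)
        profiles = [event_profile(e, settings) for e in events]
        avg = an.register_and_average(profiles)
        tip = float(avg.green[np.abs(avg.positions) <= 512].max())
        lat_sel = (avg.positions >= 768) & (avg.positions <= 1024)
        lattice = float(np.median(avg.green[lat_sel]))
        row = {
            "multiplier": mult,
            "value": base_value * mult,
            "n_events": len(events),
            "tip_intensity": tip,
            "lattice_intensity": lattice,
            "tip_lattice_ratio": tip / lattice if lattice else np.nan,
        }
        if reference_profile is not None:
            errs = []
            for pr in profiles:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rel = an.register_and_average([pr])
                errs.append(
                    an.profile_error(
                        _crop(rel, *score_window_nm),
                        _crop(reference_profile, *score_window_nm),
                    )
                )
            row["mean_profile_error"] = float(np.mean(errs))
            row["sem_profile_error"] = float(np.std(errs) / np.sqrt(len(errs)))
        out.append(row)
    return pd.DataFrame(out)


def compare_ensembles(
    a, b, test: str = "two_sample_t", paired: bool = False
) -> dict:
    """Reporting convenience: compare a metric between two simulated ensembles.

    ``test`` is one of ``paired_t`` (split-comet style within-event pairs),
    ``two_sample_t``, ``kruskal`` or ``mannwhitney``.  Returns the statistic
    and p-value; intended for simulated ensembles only.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "paired_t" or paired:
        res = stats.ttest_rel(a, b)
    elif test == "two_sample_t":
        res = stats.ttest_ind(a, b)
    elif test == "kruskal":
        res = stats.kruskal(a, b)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}


def _crop(profile: an.LineScanProfile, lo: float, hi: float) -> an.LineScanProfile:
    sel = (profile.positions >= lo) & (profile.positions <= hi)
    return an.LineScanProfile(
        positions=profile.positions[sel], red=profile.red[sel],
        green=profile.green[sel], n_averaged=profile.n_averaged,
        registered=profile.registered, flagged=profile.flagged,
    )
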