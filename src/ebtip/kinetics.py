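"""Rate laws and the exponential event-time sampler.

Every potential event (tubulin arrival/departure, lateral-bond
formation/breakage, EB1 binding/unbinding, hydrolysis) is a Poisson process
with a single-molecule rate constant ``k``; a candidate's waiting time is
drawn as ``-log(u) / k`` with ``u`` uniform on (0, 1].  At each step the
event with the shortest time executes (first-reaction selection).

Rate structure
--------------
* Tubulin arrival, per protofilament: ``k_on_tubulin * [tubulin]``.  The
  default on-rate constant is calibrated so that the total arrival rate over
  13 protofilaments is ~85 s^-1 at 10 uM tubulin.
* Tubulin departure (tip dimer only): a 6-cell table by nucleotide state and
  the dimer's current number of lateral bonds (0, 1 or 2); GTP with two
  lateral bonds is the most stable cell.  During the taper-triggered
  catastrophe boost the whole table is multiplied by ``catastrophe_boost``.
* Lateral bonds: constant formation rate per formable bond; breakage rate
  ``k_lat_break_base / pi_break`` per formed bond (``pi_break`` acts as a
  dimensionless bond-stability penalty; lowering it from 10 to 6 in the
  split-comet preset makes bonds easier to break and tapers longer).  The
  break rate is also boosted during catastrophe.
* EB1 binding, per unoccupied pocket: ``k_on_edge`` or ``k_on_closed``
  times ``[EB1]``, depending only on the pocket's structural class
  (protofilament-edge arrivals are 50-100x faster than closed-lattice
  arrivals, regardless of hydrolysis state).
* EB1 unbinding, per occupied pocket: selected by (structural class,
  nucleotide class); the closed-lattice GDP off-rate is 6-12x the GTP
  off-rate.  ``monomer_mode`` multiplies every EB1 off-rate by 4
  (coarse-grained EB1 monomers instead of dimers).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

from .lattice import BindingSite, ConfigurationError

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("GTP", "GDP")


def _default_tubulin_off_table() -> dict:
    # s^-1 per tip dimer, by (nucleotide, n_lateral_bonds).  Roughly one
    # order of magnitude of stabilization per lateral bond, with GDP
    # longitudinal bonds an order of magnitude weaker than GTP; the absolute
    # scale is calibrated to give 10-30 nm/s growth at 10 uM tubulin together
    # with the observed tip taper (see docs/methods.md).
    return {
        ("GTP", 0): 4.0,
        ("GTP", 1): 0.5,
        ("GTP", 2): 0.067,
        ("GDP", 0): 40.0,
        ("GDP", 1): 12.0,
        ("GDP", 2): 5.0,
    }


@dataclass
class KineticParameters:
    """All rate constants, concentrations and mode switches for one run."""

    # tubulin assembly
    tubulin_conc: float = 10.0  # uM
    k_on_tubulin: float = 0.654  # uM^-1 s^-1 per protofilament (~85 s^-1 total at 10 uM)
    k_off_tubulin_base: dict = field(default_factory=_default_tubulin_off_table)
    k_hydrolysis: float = 0.55  # s^-1 per non-seed GTP dimer
    k_lat_form: float = 0.5  # s^-1 per formable bond
    k_lat_break_base: float = 0.1  # s^-1; divided by pi_break
    pi_break: float = 10.0  # dimensionless bond-stability penalty
    catastrophe_boost: float = 100.0  # off/break multiplier when taper rule trips
    max_taper_dimers: int = 75  # taper threshold (75 dimers = 600 nm)

    # EB1
    eb1_conc: float = 50.0  # nM
    k_on_edge: float = 4.7e-3  # nM^-1 site^-1 s^-1 (50x closed)
    k_on_closed: float = 9.4e-5  # nM^-1 site^-1 s^-1
    k_off_closed_GTP: float = 0.11 / 12  # s^-1
    k_off_closed_GDP: float = 0.11  # s^-1 (12:1 GDP:GTP)
    k_off_edge_GTP: float = 0.11 / 12  # s^-1
    k_off_edge_GDP: float = 0.05  # s^-1

    # mode switches
    monomer_mode: bool = False  # all EB1 off-rates x4
    flare_mode: bool = False  # edge classification distal of last lateral bond

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ConfigurationError(f"{f.name} must be >= 0, got {v}")
        for key, v in self.k_off_tubulin_base.items():
            if v < 0:
                raise ConfigurationError(f"k_off_tubulin_base[{key}] must be >= 0")
        if self.pi_break <= 0:
            raise ConfigurationError("pi_break must be > 0")

    # ------------------------------------------------------------------ #
    # derived dimensionless ratios

    @property
    def edge_closed_on_ratio(self) -> float:
        return self.k_on_edge / self.k_on_closed

    @property
    def gdp_gtp_off_ratio(self) -> float:
        return self.k_off_closed_GDP / self.k_off_closed_GTP

    def with_overrides(self, **overrides) -> "KineticParameters":
        return replace(self, **overrides)


# ---------------------------------------------------------------------- #
# provenance of default values, logged by the config loader

PARAMETER_PROVENANCE = {
    "tubulin_conc": "printed-in-paper",
    "k_on_tubulin": "derived-from-ratio",  # fixed by ~85 s^-1 total at 10 uM
    "k_off_tubulin_base": "repo-default",
    "k_hydrolysis": "printed-in-paper",
    "k_lat_form": "repo-default",
    "k_lat_break_base": "repo-default",
    "pi_break": "printed-in-paper",
    "catastrophe_boost": "repo-default",
    "max_taper_dimers": "printed-in-paper",
    "eb1_conc": "repo-default",
    "k_on_edge": "derived-from-ratio",  # inside printed sweep band, 50:1 vs closed
    "k_on_closed": "derived-from-ratio",  # inside printed sweep band
    "k_off_closed_GTP": "repo-default",
    "k_off_closed_GDP": "derived-from-ratio",  # 12:1 GDP:GTP
    "k_off_edge_GTP": "repo-default",
    "k_off_edge_GDP": "repo-default",
    "monomer_mode": "repo-default",
    "flare_mode": "repo-default",
}


def load_parameters(path) -> KineticParameters:
    """Read kinetic parameters from a YAML mapping; unset keys take defaults.

    The tubulin off-rate table may be given as ``k_off_tubulin_base:
    {GTP: [r0, r1, r2], GDP: [r0, r1, r2]}`` (rates by lateral-bond count).
    Emits one provenance log line per parameter.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(KineticParameters)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
    if "k_off_tubulin_base" in raw:
        tab = raw["k_off_tubulin_base"]
        raw["k_off_tubulin_base"] = {
            (nuc, b): float(tab[nuc][b]) for nuc in NUCLEOTIDES for b in range(3)
        }
    params = KineticParameters(**raw)
    for f in fields(KineticParameters):
        src = "config-file" if f.name in raw else PARAMETER_PROVENANCE[f.name]
        logger.info("parameter %s = %r [%s]", f.name, getattr(params, f.name), src)
    return params


def dump_parameters(params: KineticParameters, path) -> None:
    """Write the fully resolved parameter set as YAML (config echo)."""
    d = {}
    for f in fields(KineticParameters):
        v = getattr(params, f.name)
        if f.name == "k_off_tubulin_base":
            v = {nuc: [float(v[(nuc, b)]) for b in range(3)] for nuc in NUCLEOTIDES}
        d[f.name] = v
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------- #
# rate laws


def draw_event_time(k: float, rng: np.random.Generator) -> float:
    """Waiting time ``-log(u) / k`` for one candidate with rate ``k`` (s^-1)."""
    if k <= 0:
        raise ConfigurationError("rate must be > 0 for a candidate event")
    u = 1.0 - rng.random()  # uniform on (0, 1]
    return -math.log(u) / k


def tubulin_arrival_rate(params: KineticParameters) -> float:
    """Tubulin arrival rate per protofilament, s^-1."""
    return params.k_on_tubulin * params.tubulin_conc


def tubulin_off_rate(
    nucleotide: str, n_lateral_bonds: int, boosted: bool, params: KineticParameters
) -> float:
    """Departure rate of a tip dimer, s^-1."""
    if n_lateral_bonds not in (0, 1, 2):
        raise ConfigurationError(f"n_lateral_bonds must be 0, 1 or 2, got {n_lateral_bonds}")
    if nucleotide not in NUCLEOTIDES:
        raise ConfigurationError(f"unknown nucleotide {nucleotide!r}")
    rate = params.k_off_tubulin_base[(nucleotide, n_lateral_bonds)]
    if boosted:
        rate *= params.catastrophe_boost
    return rate


def lateral_bond_rates(params: KineticParameters, boosted: bool = False) -> tuple[float, float]:
    """(k_form, k_break) per bond, s^-1; break rate = base / pi_break (x boost)."""
    k_break = params.k_lat_break_base / params.pi_break
    if boosted:
        k_break *= params.catastrophe_boost
    return params.k_lat_form, k_break


def eb1_on_rate(structural_class: str, params: KineticParameters) -> float:
    """EB1 arrival rate to one unoccupied pocket, s^-1 (nucleotide-independent)."""
    k = params.k_on_edge if structural_class == "edge" else params.k_on_closed
    return k * params.eb1_conc


def eb1_off_rate(
    structural_class: str, nucleotide_class: str, params: KineticParameters
) -> float:
    """EB1 departure rate from one occupied pocket, s^-1."""
    rate = {
        ("closed", "GTP"): params.k_off_closed_GTP,
        ("closed", "GDP"): params.k_off_closed_GDP,
        ("edge", "GTP"): params.k_off_edge_GTP,
        ("edge", "GDP"): params.k_off_edge_GDP,
    }[(structural_class, nucleotide_class)]
    if params.monomer_mode:
        rate *= 4.0
    return rate


def eb1_rates(site: BindingSite, params: KineticParameters) -> tuple[float, float]:
    """(k_on_total, k_off) for one pocket; only the feasible one is meaningful."""
    return (
        eb1_on_rate(site.structural_class, params),
        eb1_off_rate(site.structural_class, site.nucleotide_class, params),
    )
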