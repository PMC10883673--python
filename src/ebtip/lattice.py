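"""Microtubule lattice data model and EB1 binding-site classification.

The microtubule is represented as ``n_pf`` (default 13) protofilaments of
tubulin dimers on a 2D index sheet with a circular seam: protofilament
``n_pf - 1`` shares lateral bonds with protofilament 0.  Lateral neighbours
are paired at equal longitudinal index (no helical offset); the offset is
irrelevant to every quantity measured downstream.

Each dimer carries a nucleotide state (GTP or GDP) and two lateral-bond
flags.  Protofilaments are contiguous from the minus end (index 0) to their
tip, and the first ``seed_length`` dimers form a stabilized GTP seed that is
never hydrolyzed or removed (the in-silico analogue of a GMPCPP seed).

An EB1 binding pocket sits at the interface between two adjacent
protofilaments and is made of up to four dimers: two longitudinally adjacent
dimers on each protofilament, at heights ``j`` (minus-end-ward) and
``j + 1``.  A pocket with all four member dimers present is a *closed*
lattice site; a pocket with only two or three members (at a protofilament
tip, along the side of an exposed protofilament, or at a lattice opening) is
a *protofilament-edge* site.  The pocket's nucleotide class is GDP as soon
as at least one of the two minus-end-ward member dimers has hydrolyzed.

All longitudinal indices in this package are 0-based, minus end to plus end;
lengths are stored in dimers (8 nm each) and reported in nm externally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np
import pandas as pd

#: Axial extent of one tubulin dimer, nm.
DIMER_LENGTH_NM = 8.0

#: Minimum number of member dimers for a binding pocket to exist.  A pocket
#: with 2 or 3 members is a single protofilament-edge site; with all 4 it is
#: a closed-lattice site.  The two members may sit on one protofilament
#: (exposed side) or one on each (interface tip).
MIN_POCKET_MEMBERS = 2


class ConfigurationError(ValueError):
    """Invalid construction arguments or parameter values."""


class InfeasibleEventError(RuntimeError):
    """An event was applied that is not feasible in the current state."""


class EventKind(Enum):
    TUBULIN_ON = "tubulin_on"
    TUBULIN_OFF = "tubulin_off"
    LAT_FORM = "lat_form"
    LAT_BREAK = "lat_break"
    EB1_ON = "eb1_on"
    EB1_OFF = "eb1_off"
    HYDROLYSIS = "hydrolysis"


@dataclass(frozen=True)
class Event:
    """A single state transition of the lattice.

    ``pf`` identifies a protofilament (tubulin events, hydrolysis);
    ``interface`` identifies the seam between protofilament ``interface``
    and ``(interface + 1) % n_pf`` (bond and EB1 events); ``j`` is the
    0-based longitudinal index (bond height, pocket base height, or the
    hydrolyzed dimer's height).
    """

    kind: EventKind
    pf: int = -1
    interface: int = -1
    j: int = -1


@dataclass(frozen=True)
class BindingSite:
    """An EB1 binding pocket at ``(interface, j)``.

    ``structural_class`` is ``"edge"`` or ``"closed"``; ``nucleotide_class``
    is ``"GTP"`` or ``"GDP"``; ``n_members`` counts the existing member
    dimers (2-4).
    """

    interface: int
    j: int
    structural_class: str
    nucleotide_class: str
    n_members: int
    occupied: bool
    origin_class_at_binding: str = "none"


class Lattice:
    """Mutable 13-protofilament microtubule lattice state.

    Backed by fixed-capacity numpy arrays:

    - ``length[p]``      : dimers on protofilament ``p``
    - ``gdp[p, j]``      : 1 if dimer ``(p, j)`` has hydrolyzed to GDP
    - ``bond[i, j]``     : 1 if the lateral bond between protofilaments
      ``i`` and ``(i + 1) % n_pf`` at height ``j`` is formed
    - ``occ[i, j]``      : 1 if the pocket at ``(i, j)`` holds an EB1
    - ``origin[i, j]``   : the pocket's structural class when its current
      occupant bound (1 = edge, 2 = closed, 0 = unoccupied)
    """

    def __init__(self, n_pf: int = 13, seed_length: int = 25, capacity: int = 512):
        if n_pf < 2 or seed_length < 2:
            raise ConfigurationError(
                f"need n_pf >= 2 and seed_length >= 2, got {n_pf}, {seed_length}"
            )
        if capacity <= seed_length:
            raise ConfigurationError("capacity must exceed seed_length")
        self.n_pf = n_pf
        self.seed_length = seed_length
        self.capacity = capacity
        self.length = np.full(n_pf, seed_length, dtype=np.int64)
        self.gdp = np.zeros((n_pf, capacity), dtype=np.uint8)
        self.bond = np.zeros((n_pf, capacity), dtype=np.uint8)
        self.occ = np.zeros((n_pf, capacity), dtype=np.uint8)
        self.origin = np.zeros((n_pf, capacity), dtype=np.uint8)
        # all possible lateral bonds within the seed start formed
        self.bond[:, :seed_length] = 1
        # running tallies of occupancy bookkeeping (conservation invariant)
        self.n_bind_events = 0
        self.n_unbind_events = 0
        self.n_forced_releases = 0

    # ------------------------------------------------------------------ #
    # geometry helpers

    def right_neighbor(self, pf: int) -> int:
        return (pf + 1) % self.n_pf

    def dimer_exists(self, pf: int, j: int) -> bool:
        return 0 <= j < self.length[pf]

    def n_members(self, interface: int, j: int) -> int:
        """Number of existing member dimers of pocket ``(interface, j)``."""
        r = self.right_neighbor(interface)
        mi = int(np.clip(self.length[interface] - j, 0, 2))
        mr = int(np.clip(self.length[r] - j, 0, 2))
        return mi + mr

    def most_distal_bond(self, interface: int) -> int:
        """Height of the most distal formed lateral bond on an interface, or -1."""
        col = self.bond[interface, : int(self.length.max())]
        idx = np.nonzero(col)[0]
        return int(idx[-1]) if idx.size else -1

    def site_class(self, interface: int, j: int, flare_mode: bool = False) -> str | None:
        """Structural class of pocket ``(interface, j)``; None if it does not exist.

        In flare mode every pocket distal of the interface's most distal
        lateral bond is a protofilament-edge site, approximating
        protofilaments that curve away from the tube axis.
        """
        m = self.n_members(interface, j)
        if m < MIN_POCKET_MEMBERS:
            return None
        if m < 4:
            return "edge"
        if flare_mode and j > self.most_distal_bond(interface):
            return "edge"
        return "closed"

    def site_nucleotide(self, interface: int, j: int) -> str:
        """GDP iff >= 1 of the two minus-end-ward member dimers is GDP."""
        r = self.right_neighbor(interface)
        if self.gdp[interface, j] or self.gdp[r, j]:
            return "GDP"
        return "GTP"

    def taper_length(self) -> float:
        """Tip taper: longest minus second-shortest protofilament, in nm."""
        srt = np.sort(self.length)
        return float(srt[-1] - srt[1]) * DIMER_LENGTH_NM

    # ------------------------------------------------------------------ #
    # site enumeration

    def iter_sites(
        self, flare_mode: bool = False, flare_clamp_dimers: int = 0
    ) -> Iterator[BindingSite]:
        """Yield every existing binding pocket.

        ``flare_clamp_dimers`` (experimental) artificially moves the
        effective most-distal lateral bond ``n`` dimers toward the minus
        end, emulating increased tip flaring; it only matters with
        ``flare_mode`` on.
        """
        for i in range(self.n_pf):
            mdb = self.most_distal_bond(i) - flare_clamp_dimers if flare_mode else -1
            r = self.right_neighbor(i)
            top = max(int(self.length[i]), int(self.length[r]))
            for j in range(top):
                m = self.n_members(i, j)
                if m < MIN_POCKET_MEMBERS:
                    continue
                if m == 4 and not (flare_mode and j > mdb):
                    cls = "closed"
                else:
                    cls = "edge"
                origin = {0: "none", 1: "edge", 2: "closed"}[int(self.origin[i, j])]
                yield BindingSite(
                    interface=i,
                    j=j,
                    structural_class=cls,
                    nucleotide_class=self.site_nucleotide(i, j),
                    n_members=m,
                    occupied=bool(self.occ[i, j]),
                    origin_class_at_binding=origin,
                )

    # ------------------------------------------------------------------ #
    # event application

    def apply_event(self, event: Event) -> list[tuple[int, int]]:
        """Apply one event in place.

        Returns the list of ``(interface, j)`` pockets whose EB1 was force-
        released because the pocket dropped below 2 member dimers.  An EB1
        bound to a pocket that gains its fourth member simply remains bound
        and is thereafter classified closed ("locked in").
        """
        k = event.kind
        if k is EventKind.TUBULIN_ON:
            p = event.pf
            h = int(self.length[p])
            if h >= self.capacity:
                raise InfeasibleEventError("lattice capacity exhausted")
            self.gdp[p, h] = 0
            self.length[p] = h + 1
            return []
        if k is EventKind.TUBULIN_OFF:
            p = event.pf
            h = int(self.length[p]) - 1
            if h < self.seed_length:
                raise InfeasibleEventError("cannot remove a seed dimer")
            self.length[p] = h
            self.gdp[p, h] = 0
            # lateral bonds of the departing dimer vanish with it
            left = (p - 1) % self.n_pf
            for i in (left, p):
                self.bond[i, h] = 0
            # pockets containing the departed dimer may cease to exist
            released = []
            for i in (left, p):
                for j in (h - 1, h):
                    if j < 0:
                        continue
                    if self.occ[i, j] and self.n_members(i, j) < MIN_POCKET_MEMBERS:
                        self.occ[i, j] = 0
                        self.origin[i, j] = 0
                        self.n_forced_releases += 1
                        released.append((i, j))
            return released
        if k is EventKind.LAT_FORM:
            i, j = event.interface, event.j
            r = self.right_neighbor(i)
            if not (self.dimer_exists(i, j) and self.dimer_exists(r, j)):
                raise InfeasibleEventError("bond partners do not both exist")
            if self.bond[i, j]:
                raise InfeasibleEventError("bond already formed")
            self.bond[i, j] = 1
            return []
        if k is EventKind.LAT_BREAK:
            i, j = event.interface, event.j
            if not self.bond[i, j]:
                raise InfeasibleEventError("cannot break a nonexistent bond")
            self.bond[i, j] = 0
            return []
        if k is EventKind.EB1_ON:
            i, j = event.interface, event.j
            cls = self.site_class(i, j)
            if cls is None:
                raise InfeasibleEventError("binding pocket does not exist")
            if self.occ[i, j]:
                raise InfeasibleEventError("pocket already occupied")
            self.occ[i, j] = 1
            self.origin[i, j] = 1 if cls == "edge" else 2
            self.n_bind_events += 1
            return []
        if k is EventKind.EB1_OFF:
            i, j = event.interface, event.j
            if not self.occ[i, j]:
                raise InfeasibleEventError("pocket not occupied")
            self.occ[i, j] = 0
            self.origin[i, j] = 0
            self.n_unbind_events += 1
            return []
        if k is EventKind.HYDROLYSIS:
            p, j = event.pf, event.j
            if not self.dimer_exists(p, j):
                raise InfeasibleEventError("dimer does not exist")
            if j < self.seed_length:
                raise InfeasibleEventError("seed dimers never hydrolyze")
            if self.gdp[p, j]:
                raise InfeasibleEventError("dimer already GDP")
            self.gdp[p, j] = 1
            return []
        raise InfeasibleEventError(f"unknown event kind {k}")

    # ------------------------------------------------------------------ #
    # invariants & export

    def n_bound(self) -> int:
        return int(sum(self.occ[i, : int(self.length.max())].sum() for i in range(self.n_pf)))

    def check_invariants(self) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        assert np.all(self.length >= self.seed_length), "protofilament shorter than seed"
        assert np.all(self.gdp[:, : self.seed_length] == 0), "seed dimer hydrolyzed"
        for i in range(self.n_pf):
            r = self.right_neighbor(i)
            top = int(max(self.length[i], self.length[r]))
            b = self.bond[i, :]
            js = np.nonzero(b[: self.capacity])[0]
            assert np.all(js < min(self.length[i], self.length[r])), (
                "lateral bond without both partner dimers"
            )
            for j in np.nonzero(self.occ[i, : top + 1])[0]:
                assert self.n_members(i, int(j)) >= MIN_POCKET_MEMBERS, (
                    "occupied pocket with < 2 member dimers"
                )
        bal = self.n_bind_events - self.n_unbind_events - self.n_forced_releases
        assert self.n_bound() == bal, "EB1 occupancy conservation violated"

    def to_dataframe(self) -> pd.DataFrame:
        """One row per dimer: pf, index, nucleotide, bond flags."""
        rows = []
        for p in range(self.n_pf):
            left = (p - 1) % self.n_pf
            for j in range(int(self.length[p])):
                rows.append(
                    {
                        "pf": p,
                        "index": j,
                        "nucleotide": "GDP" if self.gdp[p, j] else "GTP",
                        "bond_left": bool(self.bond[left, j]),
                        "bond_right": bool(self.bond[p, j]),
                        "in_seed": j < self.seed_length,
                    }
                )
        return pd.DataFrame(rows)


def init_lattice(n_pf: int = 13, seed_length: int = 25, capacity: int = 512) -> Lattice:
    """Create a blunt all-GTP lattice of ``seed_length`` dimers per protofilament.

    All possible lateral bonds within the seed are formed and the taper is 0.
    """
    return Lattice(n_pf=n_pf, seed_length=seed_length, capacity=capacity)


def enumerate_sites(
    lattice: Lattice, flare_mode: bool = False, flare_clamp_dimers: int = 0
) -> list[BindingSite]:
    """All EB1 binding pockets with their structural and nucleotide classes."""
    return list(
        lattice.iter_sites(flare_mode=flare_mode, flare_clamp_dimers=flare_clamp_dimers)
    )


def taper_length(lattice: Lattice) -> float:
    """Tip taper in nm (longest minus second-shortest protofilament)."""
    return lattice.taper_length()
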