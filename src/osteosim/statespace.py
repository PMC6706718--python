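"""Expanded (tunnel) state space shared by the microsimulation and the
deterministic cohort trace.

The seven-state model becomes duration-dependent through three clocks: the
two-cycle acute (first-year) fracture tunnels, the 5-year same-site
re-fracture elevation, and first-year versus subsequent excess mortality.
This module enumerates every reachable combination of macro state and
per-site time-since-fracture clock (in cycles, capped at 10 = 5 years) by
breadth-first search, and precomputes the static transition and attribute
arrays the engine needs. The expansion keeps the process Markovian, so the
cohort trace is the exact expectation of the individual simulation.

Clock convention: a fracture during cycle t puts the patient in the acute
tunnel at cycle t+1 with clock 0; the two acute cycles are clocks 0 and 1;
post states begin at clock 2 (one year after the event).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .params import FRACTURE_TYPES, FractureType, HealthState, HealthStateLabel

# macro states
WELL, AC_HIP, AC_VERT, AC_WRIST, AC_OTHER, POST_HIP, POST_VERT, DEAD = range(8)
MACRO_LABELS = (
    "well", "acute_hip", "acute_vertebral", "acute_wrist", "acute_other",
    "post_hip", "post_vertebral", "dead",
)

# site order follows FRACTURE_TYPES: hip, vertebral, wrist, other_nonvertebral
N_SITES = 4
ACUTE_OF_SITE = (AC_HIP, AC_VERT, AC_WRIST, AC_OTHER)
SITE_OF_ACUTE = {AC_HIP: 0, AC_VERT: 1, AC_WRIST: 2, AC_OTHER: 3}
DEST_OF_ACUTE = {AC_HIP: POST_HIP, AC_VERT: POST_VERT, AC_WRIST: WELL, AC_OTHER: WELL}

#: fracture sites reachable per macro state (indices into FRACTURE_TYPES)
ALLOWED_SITES = {
    WELL: (0, 1, 2, 3),
    AC_HIP: (0, 1, 2, 3),
    AC_VERT: (0, 1, 2, 3),
    AC_WRIST: (0, 1, 2, 3),
    AC_OTHER: (0, 1, 2, 3),
    POST_HIP: (0,),
    POST_VERT: (0, 1),
    DEAD: (),
}

#: clock cap in cycles: at or beyond CAP there is no history elevation left
CAP = 10

# excess-mortality classes: none, first-year hip/vertebral/other, subsequent
# hip/vertebral
MORT_NONE, MORT_HIP1, MORT_VERT1, MORT_OTHER1, MORT_HIP_S, MORT_VERT_S = range(6)
_MORT_OF_MACRO = {
    WELL: MORT_NONE, AC_HIP: MORT_HIP1, AC_VERT: MORT_VERT1,
    AC_WRIST: MORT_OTHER1, AC_OTHER: MORT_OTHER1,
    POST_HIP: MORT_HIP_S, POST_VERT: MORT_VERT_S, DEAD: MORT_NONE,
}

# utility classes: well, first-year hip/vert/wrist/other, subsequent hip/vert
UTIL_WELL, UTIL_HIP1, UTIL_VERT1, UTIL_WRIST1, UTIL_OTHER1, UTIL_HIP_S, UTIL_VERT_S = range(7)
_UTIL_OF_MACRO = {
    WELL: UTIL_WELL, AC_HIP: UTIL_HIP1, AC_VERT: UTIL_VERT1,
    AC_WRIST: UTIL_WRIST1, AC_OTHER: UTIL_OTHER1,
    POST_HIP: UTIL_HIP_S, POST_VERT: UTIL_VERT_S, DEAD: UTIL_WELL,
}


class StateSpaceError(RuntimeError):
    """Raised when the expanded state space exceeds the configured bound."""


def _advance(clocks: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(min(c + 1, CAP) for c in clocks)


def _mask(macro: int, clocks: tuple[int, ...]) -> tuple[int, ...]:
    """Drop clocks that can no longer influence anything in ``macro``."""
    if macro == POST_HIP:
        return (clocks[0], CAP, CAP, CAP)
    if macro == POST_VERT:
        return (clocks[0], clocks[1], CAP, CAP)
    if macro == DEAD:
        return (CAP,) * 4
    return clocks


def _stay_next(state: tuple[int, tuple[int, ...]]) -> tuple[int, tuple[int, ...]]:
    macro, clocks = state
    if macro == DEAD:
        return state
    ncl = _advance(clocks)
    if macro in SITE_OF_ACUTE and clocks[SITE_OF_ACUTE[macro]] == 1:
        dest = DEST_OF_ACUTE[macro]
        return (dest, _mask(dest, ncl))
    return (macro, _mask(macro, ncl))


def _frac_next(state: tuple[int, tuple[int, ...]], site: int) -> tuple[int, tuple[int, ...]]:
    _, clocks = state
    ncl = list(_advance(clocks))
    ncl[site] = 0
    return (ACUTE_OF_SITE[site], tuple(ncl))


class StateSpace:
    """Reachable expanded states with precomputed transition/attribute arrays."""

    def __init__(self) -> None:
        start_well = (WELL, (CAP,) * 4)
        # prevalent vertebral fracture at baseline: post-vertebral, clock at
        # one year
        start_prevalent = (POST_VERT, (CAP, 2, CAP, CAP))
        seen: dict[tuple, int] = {}
        frontier = [start_well, start_prevalent, (DEAD, (CAP,) * 4)]
        for s in frontier:
            seen[s] = len(seen)
        queue = list(frontier)
        while queue:
            s = queue.pop()
            macro, _ = s
            succs = [_stay_next(s)]
            succs += [_frac_next(s, i) for i in ALLOWED_SITES[macro]]
            for nxt in succs:
                if nxt not in seen:
                    seen[nxt] = len(seen)
                    queue.append(nxt)

        self.states: list[tuple[int, tuple[int, ...]]] = [None] * len(seen)
        for s, i in seen.items():
            self.states[i] = s
        self.n = len(self.states)
        self.index = seen
        self.start_index = seen[start_well]
        self.prevalent_index = seen[start_prevalent]
        self.dead_index = seen[(DEAD, (CAP,) * 4)]

        self.macro = np.array([m for m, _ in self.states], dtype=np.int8)
        self.clock = np.array([c for _, c in self.states], dtype=np.int16)
        self.alive = self.macro != DEAD
        self.mort_class = np.array([_MORT_OF_MACRO[m] for m, _ in self.states], dtype=np.int8)
        self.util_class = np.array([_UTIL_OF_MACRO[m] for m, _ in self.states], dtype=np.int8)
        self.next_stay = np.array([seen[_stay_next(s)] for s in self.states], dtype=np.int32)
        nf = np.full((self.n, N_SITES), -1, dtype=np.int32)
        allowed = np.zeros((self.n, N_SITES), dtype=bool)
        for i, s in enumerate(self.states):
            for site in ALLOWED_SITES[s[0]]:
                nf[i, site] = seen[_frac_next(s, site)]
                allowed[i, site] = True
        self.next_frac = nf
        self.site_allowed = allowed

    def acute_site_of(self, idx: int):
        macro = int(self.macro[idx])
        return SITE_OF_ACUTE.get(macro)

    def health_state(self, idx: int) -> HealthState:
        """Collapse an expanded state to the model's seven-state description."""
        macro = int(self.macro[idx])
        if macro == WELL:
            return HealthState(label=HealthStateLabel.WELL)
        if macro == DEAD:
            return HealthState(label=HealthStateLabel.DEAD)
        if macro == POST_HIP:
            return HealthState(label=HealthStateLabel.POST_HIP)
        if macro == POST_VERT:
            return HealthState(label=HealthStateLabel.POST_VERTEBRAL)
        site = SITE_OF_ACUTE[macro]
        return HealthState(
            label=HealthStateLabel.ACUTE_FRACTURE, fracture=FRACTURE_TYPES[site]
        )

    def months_since_fracture(self, idx: int, cycle_months: float) -> dict[FractureType, float | None]:
        out = {}
        for site, ft in enumerate(FRACTURE_TYPES):
            c = int(self.clock[idx, site])
            out[ft] = None if c >= CAP else c * cycle_months
        return out


@lru_cache(maxsize=1)
def get_state_space() -> StateSpace:
    return StateSpace()
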