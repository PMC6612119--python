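"""Clonal growth and competition arithmetic.

Cumulative population doublings (CPD) over a culture interval is
log2(N_final / N_seed); dividing by the interval gives a clone's doubling
rate. Compounding single-culture rates predicts the clone composition of a
co-culture (the "expected" curves), against which observed flow-cytometry
fractions reveal interaction effects. Also here: stress-survival
re-weighting of a composition, mix-normalized invasion ratios, and the
caliper tumor-volume formula D * d^2 / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CloneGrowthRecord:
    """One clone's growth over one interval, with derived CPD and rate."""

    clone: str
    n_seed: float
    n_final: float
    interval: float

    @property
    def cpd(self) -> float:
        return cpd(self.n_seed, self.n_final)

    @property
    def rate(self) -> float:
        return cpd_rate(self.cpd, self.interval)


@dataclass
class CompositionState:
    """Clone fractions of a population at one timepoint."""

    timepoint: float
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        vals = list(self.fractions.values())
        if any(f < -1e-12 or f > 1 + 1e-12 for f in vals):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {sum(vals)}, expected 1")


def cpd(n_seed: float, n_final: float) -> float:
    """Cumulative population doublings:
    (log10 N_final - log10 N_seed) / log10(2) = log2(N_final / N_seed)."""
    if n_seed <= 0 or n_final <= 0:
        raise ValueError("cell counts must be positive")
    return (math.log10(n_final) - math.log10(n_seed)) / math.log10(2)


def cpd_rate(doublings: float, interval: float) -> float:
    """Doublings per day over a culture interval."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    return doublings / interval


def cpds_from_growth(growth: pd.DataFrame, passage_every: int) -> pd.DataFrame:
    """Per-clone, per-passage CPDs and rates from a growth table.

    Expects the ``simulate_growth`` schema (day, clone, cells_counted,
    cells_seeded): each interval runs from one reseeding to the next count.
    """
    rows = []
    for clone, sub in growth.groupby("clone", sort=False):
        sub = sub.sort_values("day").set_index("day")
        for end in range(passage_every, int(sub.index.max()) + 1, passage_every):
            seeded = sub.loc[end - passage_every, "cells_seeded"]
            counted = sub.loc[end, "cells_counted"]
            doublings = cpd(seeded, counted)
            rows.append(
                dict(
                    clone=clone,
                    day_start=end - passage_every,
                    day_end=end,
                    cpd=doublings,
                    rate=cpd_rate(doublings, passage_every),
                )
            )
    return pd.DataFrame(rows)


def expected_composition(
    rates: dict[str, float],
    start_fractions: dict[str, float],
    t: float,
) -> CompositionState:
    """Clone fractions after ``t`` days of compounding single-culture rates:
    f_i(t) = f_i * 2**(r_i t) / sum_j f_j * 2**(r_j t). Invariant under the
    uniform rescaling that passaging applies."""
    if set(rates) != set(start_fractions):
        raise ValueError("rates and start_fractions must name the same clones")
    clones = list(rates)
    f = np.array([start_fractions[c] for c in clones], dtype=float)
    r = np.array([rates[c] for c in clones], dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("rates must be finite")
    w = f * np.exp2(r * t)
    w = w / w.sum()
    return CompositionState(timepoint=t, fractions=dict(zip(clones, w)))


def expected_timecourse(
    rates: dict[str, float],
    start_fractions: dict[str, float],
    timepoints: list[float],
) -> list[CompositionState]:
    """Expected composition at each timepoint, compounding fixed day-0 rates."""
    return [expected_composition(rates, start_fractions, t) for t in timepoints]


def compare_expected_observed(
    expected: CompositionState,
    observed: CompositionState,
) -> pd.DataFrame:
    """Per-clone deviation table: observed - expected in percentage points,
    and the observed/expected ratio (infinite where expected is 0)."""
    if set(expected.fractions) != set(observed.fractions):
        raise ValueError("expected and observed must name the same clones")
    if expected.timepoint != observed.timepoint:
        raise ValueError("expected and observed are at different timepoints")
    rows = []
    for clone in expected.fractions:
        e, o = expected.fractions[clone], observed.fractions[clone]
        rows.append(
            dict(
                clone=clone,
                timepoint=expected.timepoint,
                expected_pct=100 * e,
                observed_pct=100 * o,
                deviation_points=100 * (o - e),
                ratio=(o / e) if e > 0 else (math.inf if o > 0 else math.nan),
            )
        )
    return pd.DataFrame(rows)


def apply_stress(state: CompositionState, survival: dict[str, float]) -> CompositionState:
    """Re-weight a composition by per-clone survival fractions (e.g. after an
    arsenite pulse): f_i <- f_i s_i / sum_j f_j s_j."""
    if set(survival) != set(state.fractions):
        raise ValueError("survival must name the same clones as the composition")
    if any(s < 0 or s > 1 for s in survival.values()):
        raise ValueError("survival fractions must lie in [0, 1]")
    total = sum(state.fractions[c] * survival[c] for c in survival)
    if total <= 0:
        raise ValueError("no clone survives: all survival-weighted fractions are 0")
    return CompositionState(
        timepoint=state.timepoint,
        fractions={c: state.fractions[c] * survival[c] / total for c in state.fractions},
    )


@dataclass(frozen=True)
class InvasionCondition:
    """Seeded and invading cell counts for one clone in one condition."""

    clone: str
    seeded: float
    invading: float
    condition: str  # alone | mix


def mix_invasion_ratio(alone: InvasionCondition, in_mix: InvasionCondition) -> float:
    """Per-cell invasion in the mix relative to the clone alone:
    (invading_mix / seeded_mix) / (invading_alone / seeded_alone).

    A clone contributing half the seeded cells of a mix but matching its
    solo invader count therefore scores 2.0. Returns NaN when the clone did
    not invade alone (undefined ratio) and 0.0 when it did not invade in
    the mix.
    """
    if alone.seeded <= 0 or in_mix.seeded <= 0:
        raise ValueError("seeded counts must be positive")
    if alone.invading == 0:
        return math.nan
    return (in_mix.invading / in_mix.seeded) / (alone.invading / alone.seeded)


def tumor_volume(D: float, d: float) -> float:
    """Caliper tumor volume D * d**2 / 2, with D the largest and d the
    smallest diameter (mm -> mm^3)."""
    if d <= 0:
        raise ValueError("diameters must be positive")
    if d > D:
        raise ValueError("d must not exceed D (D is the largest diameter)")
    return D * d * d / 2.0
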