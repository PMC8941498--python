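"""Paired birth-death simulations of refugial vs. non-refugial communities.

The experiment asks whether reduced extinction alone can produce
phylogenetically underdispersed communities.  Two communities of identical
target richness diversify from a single ancestor under identical per-lineage
speciation (lambda) and background extinction (mu) rates through three epochs
separated by two instantaneous mass-extinction events; they differ only in
the per-event survival probability x (each extant lineage survives an event
independently with probability x).  The "stable" (refugium) arm has survival
near 1; the "unstable" arm survives at a lower rate, optionally tied to the
stable arm by the proportionality map x_stable = 0.9 + 0.1 * x_unstable.

Each replicate runs until the extant lineage count first reaches the richness
target after the final event, prunes extinct lineages, and records the MPD
and MNTD of the reconstructed (extant, ultrametric) tree.  Across replicates
the stable-minus-unstable contrast in MPD/MNTD is summarised by Welch t-tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo_metrics import mntd_from_matrix, mpd_from_matrix

__all__ = [
    "EpochSchedule",
    "SimScenario",
    "SimReplicate",
    "SimExperiment",
    "ReplicateFailure",
    "stable_survival",
    "default_event_times",
    "simulate_bd_mass_extinction",
    "simulate_pair",
    "run_experiment",
    "preset_scenarios",
]


def stable_survival(x_unstable: float) -> float:
    """Survival probability of the stable (refugium) arm implied by the
    proportionality rule x_stable = 0.9 + 0.1 * x_unstable.

    Always lies in [0.9, 1.0]: the refugium converts an unstable per-event
    extinction of (1 - x) into a tenfold smaller one.
    """
    if not 0.0 <= x_unstable <= 1.0:
        raise ValueError("x_unstable must lie in [0, 1]")
    return 0.9 + 0.10 * x_unstable


def default_event_times(richness_target: int) -> tuple[float, float]:
    """Shipped event times: chosen so the expected pre-event lineage count
    under the net rate lambda - mu stays well below the richness target."""
    return (1.2, 2.4) if richness_target >= 50 else (0.5, 1.0)


@dataclass(frozen=True)
class EpochSchedule:
    """Mass-extinction events at fixed absolute times, shared across arms."""

    times: tuple[float, ...]
    survival: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.survival <= 1.0:
            raise ValueError("survival must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("event times must be strictly increasing")

    @property
    def epochs(self) -> int:
        return len(self.times) + 1


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one paired stable/unstable experiment."""

    x_unstable: float
    x_stable: float
    richness_target: int = 100
    lam: float = 1.75
    mu: float = 0.1
    event_times: tuple[float, ...] | None = None
    reps: int = 200
    seed: int = 0
    max_restarts: int = 100
    name: str = ""

    def __post_init__(self) -> None:
        if self.lam <= self.mu or self.mu < 0:
            raise ValueError("need lambda > mu >= 0")
        for x in (self.x_unstable, self.x_stable):
            if not 0.0 <= x <= 1.0:
                raise ValueError("survival probabilities must lie in [0, 1]")
        if self.reps < 2:
            raise ValueError("reps must be >= 2")
        if self.richness_target < 2:
            raise ValueError("richness_target must be >= 2")

    @property
    def times(self) -> tuple[float, ...]:
        if self.event_times is not None:
            return self.event_times
        return default_event_times(self.richness_target)

    def schedule(self, arm: str) -> EpochSchedule:
        surv = {"stable": self.x_stable, "unstable": self.x_unstable}[arm]
        return EpochSchedule(times=self.times, survival=surv)


class ReplicateFailure(RuntimeError):
    """Raised when a replicate exhausts its restart budget."""


@dataclass
class ReconstructedTree:
    """Extant-only (reconstructed) tree of one simulated community.

    Tips are contemporaneous at ``height``; ``distances`` is the tip-to-tip
    patristic matrix (2 * (height - MRCA split time)).
    """

    n_tips: int
    height: float
    distances: np.ndarray
    newick: str
    restarts: int

    def mpd(self) -> float:
        return mpd_from_matrix(self.distances)

    def mntd(self) -> float:
        return mntd_from_matrix(self.distances)


def _simulate_once(
    lam: float,
    mu: float,
    times: Sequence[float],
    survival: float,
    target: int,
    rng: np.random.Generator,
    max_events: int = 500_000,
):
    """One forward pass.  Returns (parent, btime, extant, T) or None on failure.

    Lineage bookkeeping: each lineage i has a birth time btime[i] and parent
    lineage parent[i]; a speciation at time t retires the parent and creates
    two children with btime t, so every internal split is binary and the split
    time of a pair's MRCA equals the birth time of its children.
    """
    parent = [-1]
    btime = [0.0]
    extant = [0]
    t = 0.0
    next_event = 0  # index into times
    total_rate_per_lineage = lam + mu
    p_speciate = lam / total_rate_per_lineage
    n_events = 0
    cap = max(2 * target, target + 20)
    while True:
        n_events += 1
        if n_events > max_events:
            return None
        n = len(extant)
        if n == 0:
            return None
        dt = rng.exponential(1.0 / (n * total_rate_per_lineage))
        if next_event < len(times) and t + dt >= times[next_event]:
            # mass extinction: each extant lineage survives with prob x
            t = times[next_event]
            next_event += 1
            keep = rng.random(n) < survival
            extant = [lin for lin, k in zip(extant, keep) if k]
            if not extant:
                return None
            if next_event == len(times) and len(extant) == target:
                break
            continue
        t += dt
        i = rng.integers(n)
        if rng.random() < p_speciate:
            lin = extant[i]
            for _ in range(2):
                parent.append(lin)
                btime.append(t)
            extant[i] = len(parent) - 2
            extant.append(len(parent) - 1)
        else:
            extant[i] = extant[-1]
            extant.pop()
        n = len(extant)
        if next_event == len(times):  # past the final event: stopping rule active
            if n == target:
                break
            if n >= cap:
                return None
    # extend the present past the last structural event so terminal branches
    # are strictly positive: draw the (memoryless) time to the next event
    T = t + rng.exponential(1.0 / (len(extant) * total_rate_per_lineage))
    return parent, btime, extant, T


def _reconstruct(parent, btime, extant, T) -> tuple[np.ndarray, str]:
    """Prune extinct lineages; return tip distance matrix and Newick string."""
    n = len(extant)
    tip_of = {lin: i for i, lin in enumerate(extant)}
    children: dict[int, list[int]] = {}
    for node, par in enumerate(parent):
        if par >= 0:
            children.setdefault(par, []).append(node)

    has_kept: dict[int, bool] = {}
    order: list[int] = []
    stack = [(0, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            kids = children.get(node, ())
            has_kept[node] = node in tip_of or any(has_kept[k] for k in kids)
        else:
            stack.append((node, True))
            for k in children.get(node, ()):
                stack.append((k, False))

    D = np.zeros((n, n))
    tips_under: dict[int, np.ndarray] = {}
    for node in order:
        if not has_kept[node]:
            continue
        groups = [tips_under.pop(k) for k in children.get(node, ()) if has_kept.get(k)]
        if node in tip_of:
            groups.append(np.array([tip_of[node]], dtype=int))
        if len(groups) > 1:
            split = btime[children[node][0]]  # both children born at the split
            d = 2.0 * (T - split)
            ga, gb = groups
            D[np.ix_(ga, gb)] = d
            D[np.ix_(gb, ga)] = d
            tips_under[node] = np.concatenate(groups)
        else:
            tips_under[node] = groups[0]

    # Newick of the pruned tree, unifurcations suppressed
    def render(node: int, t0: float) -> str:
        cur = node
        while True:
            if cur in tip_of:
                return f"t{tip_of[cur] + 1}:{T - t0:.10g}"
            kept = [k for k in children.get(cur, ()) if has_kept.get(k)]
            if len(kept) == 1:
                cur = kept[0]
                continue
            ts = btime[children[cur][0]]
            inner = ",".join(render(k, ts) for k in kept)
            return f"({inner}):{ts - t0:.10g}"

    newick = render(0, 0.0) + ";" if n > 1 else f"(t1:{T}):0;"
    return D, newick


def simulate_bd_mass_extinction(
    lam: float,
    mu: float,
    schedule: EpochSchedule,
    richness_target: int,
    rng: np.random.Generator,
    max_restarts: int = 100,
) -> ReconstructedTree:
    """Simulate one community tree under episodic mass extinction.

    Forward birth-death from a single lineage; at each scheduled time every
    extant lineage survives independently with the schedule's probability; the
    run stops at the first moment after the final event at which the extant
    count equals ``richness_target`` (reached by speciation, by background
    extinction, or by the event itself).  Extinct lineages are pruned, giving
    an ultrametric reconstructed tree.  Runs that die out (or overshoot beyond
    recovery) restart on a fresh substream, up to ``max_restarts``.
    """
    if schedule.survival == 0.0 and richness_target >= 1:
        warnings.warn("survival 0 at a mass-extinction event guarantees failure")
    restarts = 0
    while True:
        res = _simulate_once(
            lam, mu, schedule.times, schedule.survival, richness_target, rng
        )
        if res is not None:
            parent, btime, extant, T = res
            D, newick = _reconstruct(parent, btime, extant, T)
            return ReconstructedTree(
                n_tips=len(extant),
                height=T,
                distances=D,
                newick=newick,
                restarts=restarts,
            )
        restarts += 1
        if restarts > max_restarts:
            raise ReplicateFailure(
                f"exhausted {max_restarts} restarts "
                f"(lambda={lam}, mu={mu}, survival={schedule.survival}, "
                f"target={richness_target})"
            )


@dataclass
class SimReplicate:
    rep_index: int
    mpd_stable: float
    mntd_stable: float
    mpd_unstable: float
    mntd_unstable: float
    restarts_stable: int
    restarts_unstable: int
    newick_stable: str | None = None
    newick_unstable: str | None = None


_ARM_CODE = {"stable": 0, "unstable": 1}


def simulate_pair(
    scenario: SimScenario, rep_index: int, keep_trees: bool = False
) -> SimReplicate:
    """One paired replicate: identical rates, times and richness; the arms
    differ only in per-event survival.  Arms run on independent substreams
    derived from (scenario seed, replicate index, arm)."""
    trees = {}
    for arm in ("stable", "unstable"):
        rng = np.random.default_rng([scenario.seed, rep_index, _ARM_CODE[arm]])
        trees[arm] = simulate_bd_mass_extinction(
            scenario.lam,
            scenario.mu,
            scenario.schedule(arm),
            scenario.richness_target,
            rng,
            max_restarts=scenario.max_restarts,
        )
    return SimReplicate(
        rep_index=rep_index,
        mpd_stable=trees["stable"].mpd(),
        mntd_stable=trees["stable"].mntd(),
        mpd_unstable=trees["unstable"].mpd(),
        mntd_unstable=trees["unstable"].mntd(),
        restarts_stable=trees["stable"].restarts,
        restarts_unstable=trees["unstable"].restarts,
        newick_stable=trees["stable"].newick if keep_trees else None,
        newick_unstable=trees["unstable"].newick if keep_trees else None,
    )


@dataclass
class SimExperiment:
    """Replicate table plus Welch t-tests (stable minus unstable)."""

    scenario: SimScenario
    replicates: pd.DataFrame
    t_mpd: float
    df_mpd: float
    p_mpd: float
    t_mntd: float
    df_mntd: float
    p_mntd: float
    n_failures: int

    def summary(self) -> dict:
        r = self.replicates
        return {
            "name": self.scenario.name,
            "x_unstable": self.scenario.x_unstable,
            "x_stable": self.scenario.x_stable,
            "richness_target": self.scenario.richness_target,
            "reps": int(len(r)),
            "mean_mpd_stable": float(r["mpd_stable"].mean()),
            "mean_mpd_unstable": float(r["mpd_unstable"].mean()),
            "mean_mntd_stable": float(r["mntd_stable"].mean()),
            "mean_mntd_unstable": float(r["mntd_unstable"].mean()),
            "t_mpd": self.t_mpd,
            "df_mpd": self.df_mpd,
            "p_mpd": self.p_mpd,
            "t_mntd": self.t_mntd,
            "df_mntd": self.df_mntd,
            "p_mntd": self.p_mntd,
        }

    def histogram(self, column: str, bins: int = 20) -> pd.DataFrame:
        stable = self.replicates[f"{column}_stable"]
        unstable = self.replicates[f"{column}_unstable"]
        lo = min(stable.min(), unstable.min())
        hi = max(stable.max(), unstable.max())
        edges = np.linspace(lo, hi, bins + 1)
        cs, _ = np.histogram(stable, bins=edges)
        cu, _ = np.histogram(unstable, bins=edges)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "stable": cs, "unstable": cu}
        )


def run_experiment(scenario: SimScenario, keep_trees: bool = False) -> SimExperiment:
    """Run all replicates of a scenario and test the arm contrast.

    Aborts if more than 10% of replicates fail even after restarts.
    """
    from .comparison import welch_t

    rows = []
    failures = 0
    for rep in range(scenario.reps):
        try:
            rows.append(simulate_pair(scenario, rep, keep_trees=keep_trees))
        except ReplicateFailure:
            failures += 1
            if failures > 0.1 * scenario.reps:
                raise RuntimeError(
                    f"{failures} replicate failures out of {rep + 1} attempts; "
                    "scenario appears infeasible (check survival and target)"
                )
    reps_df = pd.DataFrame([r.__dict__ for r in rows]).drop(
        columns=["newick_stable", "newick_unstable"] if not keep_trees else []
    )
    t_mpd, df_mpd, p_mpd = welch_t(
        reps_df["mpd_stable"].to_numpy(), reps_df["mpd_unstable"].to_numpy()
    )
    t_mntd, df_mntd, p_mntd = welch_t(
        reps_df["mntd_stable"].to_numpy(), reps_df["mntd_unstable"].to_numpy()
    )
    return SimExperiment(
        scenario=scenario,
        replicates=reps_df,
        t_mpd=t_mpd,
        df_mpd=df_mpd,
        p_mpd=p_mpd,
        t_mntd=t_mntd,
        df_mntd=df_mntd,
        p_mntd=p_mntd,
        n_failures=failures,
    )


#: named survival pairs (x_unstable, x_stable); names give the per-event
#: extinction percentages unstable/stable
PRESET_SURVIVALS: dict[str, tuple[float, float]] = {
    "80-8": (0.2, 0.92),
    "30-25": (0.7, 0.75),
    "70-65": (0.3, 0.35),
    "10-1": (0.9, 0.99),
    "70-7": (0.3, 0.93),
}


def preset_scenarios(
    richness: Sequence[int] = (10, 100), reps: int = 200, seed: int = 0
) -> list[SimScenario]:
    """The canonical survival ladder at both community sizes.

    Pairs span highly disparate survival (0.2 vs 0.92), similar moderate
    (0.7 vs 0.75), similar low (0.3 vs 0.35), and the two proportionality-rule
    pairs 0.9 -> 0.99 (10%/1% extinction) and 0.3 -> 0.93 (70%/7%).
    """
    out = []
    for name, (xu, xs) in PRESET_SURVIVALS.items():
        for n in richness:
            out.append(
                SimScenario(
                    x_unstable=xu,
                    x_stable=xs,
                    richness_target=n,
                    reps=reps,
                    seed=seed,
                    name=f"{name}-n{n}",
                )
            )
    return out
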