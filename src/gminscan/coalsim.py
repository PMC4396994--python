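"""Two-population coalescent simulation with an instantaneous migration pulse.

The demographic model is secondary contact: an ancestral population of size
N splits into two descendant populations of size N at time ``tau_d`` (in
units of N generations).  Looking backward in time, lineages coalesce only
within their current population; at time ``tau_m`` (<= ``tau_d``) each
lineage then residing in population 1 independently switches to population
2 with probability ``lam`` — so, with k resident lineages, the number moved
is binomial with expectation k*lam.  This is the backward-time image of a
single burst of gene flow from population 2 into population 1.  At
``tau_d`` the two populations merge into the ancestral one.

Recombination follows Hudson's ancestral-recombination-graph construction
over a continuous unit interval: a lineage recombines at rate ``rho`` times
the breadth of its ancestral material (leftmost to rightmost endpoint), and
a uniform breakpoint splits its segments between two lineages.  Segments of
ancestral material carry the set of sample leaves they subtend; where a
coalescence makes a segment ancestral to the whole sample it has reached
its MRCA and is retired.  The simulation ends at the grand MRCA of every
position.

Mutation is infinite-sites: mutations fall as a Poisson process at rate
``theta`` per unit branch length per unit sequence, with positions uniform
on [0, 1).  Under this scaling a panmictic pair has E[pi] = theta and a
panmictic sample of n has E[S] = theta * sum_{i=1}^{n-1} 1/i (the Watterson
expectation); e.g. theta = 10 with n = 10 gives about 28 segregating sites
and theta = 150 about 424.

Times in the public API are in units of N generations; internally they are
divided by 4 into 4N-generation units in which a lineage pair coalesces at
rate 2 (so the expected pairwise within-population coalescence time is 2N
generations).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import hapstats
from .hapstats import HaplotypeWindow, distance_summary, fst_hudson, gmin

__all__ = [
    "DemographicParams",
    "GminExpectation",
    "SimulatedWindow",
    "SimulationError",
    "batch_statistics",
    "expected_gmin_mc",
    "simulate_batch",
    "simulate_window",
    "watterson_expected_s",
    "write_batch_tsv",
    "write_ms",
]

#: Hard ceiling on events per window; exceeding it raises SimulationError.
MAX_EVENTS: int = 10_000_000


class SimulationError(RuntimeError):
    """Raised when a single window exceeds the event-count ceiling."""


@dataclass(frozen=True)
class DemographicParams:
    """Secondary-contact model parameters.

    theta : population mutation rate 4*N*mu per window (> 0)
    rho   : population crossing-over rate 4*N*c per window (>= 0)
    tau_d : divergence time, units of N generations (>= 0)
    tau_m : pulse time, units of N generations (0 <= tau_m <= tau_d)
    lam   : per-lineage migration probability at the pulse, in [0, 1]
    n1    : sample size of the recipient population 1
    n2    : sample size of the source population 2
    """

    theta: float
    rho: float = 0.0
    tau_d: float = 0.0
    tau_m: float = 0.0
    lam: float = 0.0
    n1: int = 10
    n2: int = 10

    def __post_init__(self) -> None:
        if not (self.theta > 0 and math.isfinite(self.theta)):
            raise ValueError(f"theta must be finite and > 0, got {self.theta}")
        if not (self.rho >= 0 and math.isfinite(self.rho)):
            raise ValueError(f"rho must be finite and >= 0, got {self.rho}")
        if self.tau_d < 0:
            raise ValueError(f"tau_d must be >= 0, got {self.tau_d}")
        if not (0 <= self.tau_m <= self.tau_d or (self.tau_m == 0 and self.tau_d == 0)):
            raise ValueError(
                f"tau_m must satisfy 0 <= tau_m <= tau_d, got tau_m={self.tau_m}, tau_d={self.tau_d}")
        if not (0 <= self.lam <= 1):
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("n1 and n2 must each be >= 1")
        if self.n1 + self.n2 < 2:
            raise ValueError("need at least two sampled sequences")


@dataclass(frozen=True)
class SimulatedWindow:
    """One simulated window: haplotypes, migrant flag, bookkeeping."""

    window: HaplotypeWindow
    migrant_flag: bool
    n_segsites: int
    params: DemographicParams
    seed_state: Tuple[int, ...]
    positions: np.ndarray = field(compare=False, default_factory=lambda: np.empty(0))


def watterson_expected_s(theta: float, n: int) -> float:
    """Closed-form E[S] = theta * H_{n-1} for a panmictic sample of n."""
    return theta * sum(1.0 / i for i in range(1, n))


# ---------------------------------------------------------------------------
# Segment bookkeeping.  A lineage is [segments, population]; segments is a
# sorted list of (left, right, mask) tuples over [0, 1), where mask is a
# bitmask of the sample leaves the interval is ancestral to.
# ---------------------------------------------------------------------------

def _merge_segments(a, b, full_mask):
    """Coalesce two segment lists; intervals reaching the full mask retire.

    Returns ``(segments, total_length)`` with adjacent equal-mask intervals
    compacted.
    """
    out = []
    append = out.append
    length = 0.0
    i, j = 0, 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        l1, r1, m1 = a[i]
        l2, r2, m2 = b[j]
        if r1 <= l2:
            append(a[i]); length += r1 - l1; i += 1
        elif r2 <= l1:
            append(b[j]); length += r2 - l2; j += 1
        elif l1 < l2:
            append((l1, l2, m1)); length += l2 - l1
            a[i] = (l2, r1, m1)
        elif l2 < l1:
            append((l2, l1, m2)); length += l1 - l2
            b[j] = (l1, r2, m2)
        else:  # equal left endpoints: true overlap
            r = r1 if r1 < r2 else r2
            m = m1 | m2
            if m != full_mask:
                append((l1, r, m)); length += r - l1
            if r1 == r:
                i += 1
            else:
                a[i] = (r, r1, m1)
            if r2 == r:
                j += 1
            else:
                b[j] = (r, r2, m2)
    for seg in a[i:]:
        append(seg); length += seg[1] - seg[0]
    for seg in b[j:]:
        append(seg); length += seg[1] - seg[0]
    # compact adjacent intervals with identical masks
    comp = []
    cappend = comp.append
    for seg in out:
        if comp and comp[-1][2] == seg[2] and comp[-1][1] == seg[0]:
            comp[-1] = (comp[-1][0], seg[1], seg[2])
        else:
            cappend(seg)
    return comp, length


def _split_segments(segs, bp):
    """Split a segment list at ``bp``; returns (left, right, left_length)."""
    left, right = [], []
    left_len = 0.0
    for seg in segs:
        l, r, m = seg
        if r <= bp:
            left.append(seg)
            left_len += r - l
        elif l >= bp:
            right.append(seg)
        else:
            left.append((l, bp, m))
            left_len += bp - l
            right.append((bp, r, m))
    return left, right, left_len


class _Uniforms:
    """Buffered uniform(0,1) draws from a numpy Generator.

    Refilling in blocks keeps the per-draw cost at a list index instead of
    a Generator method call, which dominates the event-loop runtime.
    """

    __slots__ = ("_rng", "_buf", "_i", "_size")

    def __init__(self, rng: np.random.Generator, size: int = 4096) -> None:
        self._rng = rng
        self._size = size
        self._buf = rng.random(size).tolist()
        self._i = 0

    def __call__(self) -> float:
        i = self._i
        if i >= self._size:
            self._buf = self._rng.random(self._size).tolist()
            i = 0
        self._i = i + 1
        return self._buf[i]


def simulate_window(
    params: DemographicParams,
    rng: np.random.Generator,
    seed_state: Tuple[int, ...] = (),
) -> SimulatedWindow:
    """Simulate one independent window under the secondary-contact model."""
    n1, n2 = params.n1, params.n2
    n = n1 + n2
    full_mask = (1 << n) - 1
    theta, rho, lam = params.theta, params.rho, params.lam
    # internal time is in units of 4N generations
    merge_time = params.tau_d / 4.0
    pulse_time = params.tau_m / 4.0
    do_pulse = lam > 0 and params.tau_m < params.tau_d
    merged = merge_time <= 0.0

    # lineage = [segments, span, length]; pops hold lineage records
    pops: List[List[list]] = [[], []]
    for i in range(n):
        rec = [[(0.0, 1.0, 1 << i)], 1.0, 1.0]
        pops[0 if i < n1 else 1].append(rec)
    if merged:
        pops[0].extend(pops[1])
        pops[1] = []

    total_span = float(n) if rho > 0 else 0.0
    total_len = float(n)
    t = 0.0
    migrant_flag = False
    mutations: List[Tuple[float, int]] = []
    n_lineages = n
    events = 0
    uniform = _Uniforms(rng)
    log = math.log

    # Mutation clock: mutations arrive at rate theta * total_len.  We track
    # the accumulated intensity and fire whenever it crosses the next Exp(1)
    # threshold; within an inter-event interval the lineage configuration is
    # constant, so only the count per interval matters, not exact times.
    mut_next = -log(uniform())

    def accrue_mutations(dt: float) -> None:
        nonlocal mut_next
        area = theta * total_len * dt
        if area < mut_next:
            mut_next -= area
            return
        recs = pops[0] if not pops[1] else pops[0] + pops[1]
        while area >= mut_next:
            area -= mut_next
            mut_next = -log(uniform())
            # pick a lineage weighted by ancestral length, then a segment
            target = uniform() * total_len
            acc = 0.0
            rec = recs[-1]
            for cand in recs:
                acc += cand[2]
                if target <= acc:
                    rec = cand
                    break
            segs = rec[0]
            target = uniform() * rec[2]
            acc = 0.0
            last = len(segs) - 1
            for si in range(last + 1):
                l, r, m = segs[si]
                acc += r - l
                if target <= acc or si == last:
                    pos = r - (acc - target)
                    if pos < l:
                        pos = l
                    mutations.append((pos, m))
                    break
        mut_next -= area

    while n_lineages > 1:
        events += 1
        if events > MAX_EVENTS:
            raise SimulationError(
                f"event ceiling {MAX_EVENTS} exceeded (params={params}, seed_state={seed_state})")
        k0, k1 = len(pops[0]), len(pops[1])
        coal0 = k0 * (k0 - 1)
        coal1 = k1 * (k1 - 1)
        recomb = rho * total_span if rho > 0 else 0.0
        total_rate = coal0 + coal1 + recomb

        # next scheduled (deterministic) event, if any
        sched = None
        if do_pulse and t <= pulse_time:
            sched = ("pulse", pulse_time)
        elif not merged:
            sched = ("merge", merge_time if t < merge_time else t)

        if total_rate <= 0.0:
            if sched is None:
                raise SimulationError(
                    f"stalled with no possible events (params={params}, seed_state={seed_state})")
            t_next = sched[1]
        else:
            t_next = t - log(uniform()) / total_rate

        if sched is not None and sched[1] <= t_next:
            accrue_mutations(sched[1] - t)
            t = sched[1]
            if sched[0] == "pulse":
                do_pulse = False
                stay, move = [], []
                for rec in pops[0]:
                    (move if uniform() < lam else stay).append(rec)
                if move:
                    migrant_flag = True
                    pops[0] = stay
                    pops[1].extend(move)
            else:
                merged = True
                pops[0].extend(pops[1])
                pops[1] = []
            continue

        accrue_mutations(t_next - t)
        t = t_next
        u = uniform() * total_rate
        if u < coal0 + coal1:
            p = 0 if u < coal0 else 1
            group = pops[p]
            k = len(group)
            i = int(uniform() * k)
            if i >= k:
                i = k - 1
            j = int(uniform() * (k - 1))
            if j >= k - 1:
                j = k - 2
            if j >= i:
                j += 1
            if i > j:
                i, j = j, i
            ra, rb = group[i], group[j]
            group[j] = group[-1]
            group.pop()
            group[i] = group[-1]
            group.pop()
            total_len -= ra[2] + rb[2]
            if rho > 0:
                total_span -= ra[1] + rb[1]
            merged_segs, length = _merge_segments(ra[0], rb[0], full_mask)
            if merged_segs:
                span = (merged_segs[-1][1] - merged_segs[0][0]) if rho > 0 else 0.0
                group.append([merged_segs, span, length])
                total_len += length
                if rho > 0:
                    total_span += span
            n_lineages = len(pops[0]) + len(pops[1])
        else:
            # recombination: pick a lineage weighted by its span
            target = (u - coal0 - coal1) / rho
            acc = 0.0
            chosen = None
            chosen_pop = 0
            chosen_idx = -1
            for p in (0, 1):
                group = pops[p]
                for idx in range(len(group)):
                    acc += group[idx][1]
                    if target <= acc:
                        chosen, chosen_pop, chosen_idx = group[idx], p, idx
                        break
                if chosen is not None:
                    break
            if chosen is None:  # float round-off at the boundary
                chosen_pop = 1 if pops[1] else 0
                chosen_idx = len(pops[chosen_pop]) - 1
                chosen = pops[chosen_pop][chosen_idx]
            segs = chosen[0]
            left_end = segs[0][0]
            right_end = segs[-1][1]
            bp = left_end + uniform() * (right_end - left_end)
            if bp <= left_end or bp >= right_end:
                continue  # degenerate draw; no material changes sides
            left, right, left_len = _split_segments(segs, bp)
            group = pops[chosen_pop]
            group[chosen_idx] = group[-1]
            group.pop()
            # total ancestral length is conserved by a split; only spans change
            total_span -= chosen[1]
            group.append([left, left[-1][1] - left[0][0], left_len])
            group.append([right, right[-1][1] - right[0][0], chosen[2] - left_len])
            total_span += (left[-1][1] - left[0][0]) + (right[-1][1] - right[0][0])
            n_lineages += 1

    # assemble the 0/1 haplotype matrix, sites in positional order
    mutations.sort()
    positions = np.array([p for p, _ in mutations])
    s = len(mutations)
    if s > 0 and n <= 63:
        masks = np.array([m for _, m in mutations], dtype=np.uint64)
        matrix = ((masks[:, None] >> np.arange(n, dtype=np.uint64)) & np.uint64(1)).astype(np.int8).T
    elif s > 0:
        matrix = np.zeros((n, s), dtype=np.int8)
        for col, (_, m) in enumerate(mutations):
            for row in range(n):
                if (m >> row) & 1:
                    matrix[row, col] = 1
    else:
        matrix = np.zeros((n, 0), dtype=np.int8)

    labels = np.array([1] * n1 + [2] * n2)
    window = HaplotypeWindow(matrix, labels, window_id="sim")
    return SimulatedWindow(
        window=window,
        migrant_flag=migrant_flag,
        n_segsites=s,
        params=params,
        seed_state=tuple(seed_state),
        positions=positions,
    )


def simulate_batch(
    params: DemographicParams, n_windows: int, seed: int
) -> List[SimulatedWindow]:
    """Simulate ``n_windows`` independent windows.

    Each window uses its own counter-derived random substream, so batches
    are deterministic given (params, seed) and order-independent.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    out = []
    for w in range(n_windows):
        rng = np.random.default_rng([seed, w])
        out.append(simulate_window(params, rng, seed_state=(seed, w)))
    return out


@dataclass(frozen=True)
class GminExpectation:
    """Monte-Carlo estimate of E[G_min] under one parameterization."""

    mean: float
    n_defined: int
    n_undefined: int


def expected_gmin_mc(
    params: DemographicParams, n_windows: int, seed: int
) -> GminExpectation:
    """Monte-Carlo expectation of G_min (mean over defined windows)."""
    values = []
    n_undef = 0
    for sim in simulate_batch(params, n_windows, seed):
        g = gmin(distance_summary(sim.window, mode="count"))
        if hapstats.is_defined(g):
            values.append(g)
        else:
            n_undef += 1
    if not values:
        return GminExpectation(hapstats.UNDEFINED, 0, n_undef)
    return GminExpectation(float(np.mean(values)), len(values), n_undef)


def batch_statistics(sims: Sequence[SimulatedWindow]) -> pd.DataFrame:
    """Per-window statistics table for a simulated batch (count mode)."""
    rows = []
    for i, sim in enumerate(sims):
        summ = distance_summary(sim.window, mode="count")
        rows.append({
            "window_id": f"w{i}",
            "migrant_flag": sim.migrant_flag,
            "n_segsites": sim.n_segsites,
            "gmin": gmin(summ),
            "fst": fst_hudson(summ),
            "min_dxy": summ.min_dxy,
            "mean_dxy": summ.mean_dxy,
            "mean_dxx": summ.mean_dxx,
            "mean_dyy": summ.mean_dyy,
        })
    return pd.DataFrame(rows)


def write_batch_tsv(
    sims: Sequence[SimulatedWindow],
    path: str | Path,
    params: DemographicParams,
    seed: int,
) -> pd.DataFrame:
    """Write the batch statistics TSV plus a JSON sidecar of run metadata."""
    from . import __version__

    path = Path(path)
    df = batch_statistics(sims)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = {
        "params": {k: getattr(params, k) for k in
                   ("theta", "rho", "tau_d", "tau_m", "lam", "n1", "n2")},
        "n_windows": len(sims),
        "seed": seed,
        "version": __version__,
    }
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return df


def write_ms(sims: Sequence[SimulatedWindow], path: str | Path) -> None:
    """Dump a batch in ms-style text (//, segsites, positions, 0/1 rows)."""
    with open(path, "w") as fh:
        for sim in sims:
            fh.write("//\n")
            fh.write(f"segsites: {sim.n_segsites}\n")
            if sim.n_segsites:
                fh.write("positions: " +
                         " ".join(f"{p:.6f}" for p in sim.positions) + "\n")
                for row in sim.window.sequences:
                    fh.write("".join(str(int(x)) for x in row) + "\n")
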