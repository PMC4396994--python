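"""Outlier classification, sensitivity/specificity, parameter sweeps.

Simulated windows are classified as gene-flow "positives" when the
Z-score of a statistic (its standardized deviation from the batch mean)
falls below a threshold; the fixed thresholds are the lower-tail normal
quantiles -1.645, -2.326 and -3.090.  Windows whose simulated genealogy
contains a lineage that switched populations at the migration pulse form
the truth set M; the called set Q is the windows below the threshold.
Sensitivity is phi = |M & Q| / |M| and specificity is psi = |M & Q| / |Q|.
This is deliberately not a formal statistical test — no null distribution
is asserted and no multiple-testing correction is applied; it is an
operating-characteristic summary of the Z-score screen.

``run_grid`` evaluates these quantities over a cartesian parameter grid,
one independently simulated batch per cell, and ``variance_partition``
decomposes the between-cell variance of a response (e.g. per-cell mean
G_min) into percent sums of squares for the model parameters, treating
parameters as centered numeric covariates on a balanced full factorial
(where the decomposition is order-invariant).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import hapstats
from .coalsim import DemographicParams, simulate_batch
from .hapstats import distance_summary, fst_hudson, gmin, is_defined

__all__ = [
    "DEFAULT_THRESHOLDS",
    "GridSpec",
    "SweepResult",
    "run_grid",
    "sensitivity",
    "specificity",
    "sweep_results_frame",
    "variance_partition",
    "zscores",
]

#: Lower-tail normal quantiles used as the fixed outlier thresholds.
DEFAULT_THRESHOLDS: Tuple[float, ...] = (-1.645, -2.326, -3.090)


class ZeroSpreadError(ValueError):
    """Raised when a batch has no spread to standardize against."""


def zscores(values: Sequence[float], batch_name: str = "") -> np.ndarray:
    """Standardize values by the batch's own mean and sample SD (ddof=1).

    ``nan`` entries (undefined statistics) are excluded from the mean/SD
    and propagate as ``nan`` in the output.
    """
    x = np.asarray(values, dtype=float)
    defined = ~np.isnan(x)
    if defined.sum() < 2:
        raise ZeroSpreadError(
            f"batch {batch_name or '<unnamed>'}: need >= 2 defined values")
    mu = x[defined].mean()
    sd = x[defined].std(ddof=1)
    if sd == 0:
        raise ZeroSpreadError(
            f"batch {batch_name or '<unnamed>'}: zero spread, cannot standardize")
    z = np.full_like(x, np.nan)
    z[defined] = (x[defined] - mu) / sd
    return z


def sensitivity(M: Set, Q: Set) -> float:
    """phi = |M & Q| / |M|; nan when there are no true gene-flow windows."""
    if not M:
        return math.nan
    return len(M & Q) / len(M)


def specificity(M: Set, Q: Set) -> float:
    """psi = |M & Q| / |Q|; nan when nothing was called."""
    if not Q:
        return math.nan
    return len(M & Q) / len(Q)


@dataclass(frozen=True)
class SweepResult:
    """Aggregates for one parameter-grid cell."""

    params: DemographicParams
    n_windows: int
    n_defined: int
    mean_gmin: float
    sd_gmin: float
    mean_fst: float
    sd_fst: float
    n_true_migrant: int
    #: per-threshold counts/rates, keyed by threshold value
    n_called_gmin: Dict[float, int] = field(default_factory=dict)
    n_called_fst: Dict[float, int] = field(default_factory=dict)
    phi_gmin: Dict[float, float] = field(default_factory=dict)
    psi_gmin: Dict[float, float] = field(default_factory=dict)
    phi_fst: Dict[float, float] = field(default_factory=dict)
    psi_fst: Dict[float, float] = field(default_factory=dict)


def evaluate_batch(
    params: DemographicParams,
    n_windows: int,
    seed: int,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> SweepResult:
    """Simulate one cell, Z-standardize within it, and score M against Q.

    Windows with undefined statistics are excluded from standardization and
    from both M and Q (an undefined value cannot be an outlier).
    """
    sims = simulate_batch(params, n_windows, seed)
    g = np.empty(n_windows)
    f = np.empty(n_windows)
    migrant = np.zeros(n_windows, dtype=bool)
    for i, sim in enumerate(sims):
        summ = distance_summary(sim.window, mode="count")
        g[i] = gmin(summ)
        f[i] = fst_hudson(summ)
        migrant[i] = sim.migrant_flag

    defined = ~np.isnan(g)
    zg = zscores(g, batch_name="gmin") if defined.sum() >= 2 else np.full(n_windows, np.nan)
    zf = zscores(f, batch_name="fst") if defined.sum() >= 2 else np.full(n_windows, np.nan)

    M = set(np.flatnonzero(migrant & defined))
    res = SweepResult(
        params=params,
        n_windows=n_windows,
        n_defined=int(defined.sum()),
        mean_gmin=float(np.nanmean(g)) if defined.any() else math.nan,
        sd_gmin=float(np.nanstd(g, ddof=1)) if defined.sum() > 1 else math.nan,
        mean_fst=float(np.nanmean(f)) if defined.any() else math.nan,
        sd_fst=float(np.nanstd(f, ddof=1)) if defined.sum() > 1 else math.nan,
        n_true_migrant=len(M),
    )
    for thr in thresholds:
        Qg = set(np.flatnonzero(np.less(zg, thr, where=~np.isnan(zg), out=np.zeros(n_windows, bool))))
        Qf = set(np.flatnonzero(np.less(zf, thr, where=~np.isnan(zf), out=np.zeros(n_windows, bool))))
        res.n_called_gmin[thr] = len(Qg)
        res.n_called_fst[thr] = len(Qf)
        res.phi_gmin[thr] = sensitivity(M, Qg)
        res.psi_gmin[thr] = specificity(M, Qg)
        res.phi_fst[thr] = sensitivity(M, Qf)
        res.psi_fst[thr] = specificity(M, Qf)
    return res


@dataclass(frozen=True)
class GridSpec:
    """Cartesian parameter grid for a sweep.

    ``tau_m_fractions`` are relative pulse times; each cell uses
    ``tau_m = fraction * tau_d``.  ``sample_configs`` are (n1, n2) pairs.
    """

    theta: Tuple[float, ...]
    rho: Tuple[float, ...]
    tau_d: Tuple[float, ...]
    tau_m_fractions: Tuple[float, ...] = (0.0,)
    lam: Tuple[float, ...] = (0.0,)
    sample_configs: Tuple[Tuple[int, int], ...] = ((10, 10),)
    n_windows: int = 1000
    thresholds: Tuple[float, ...] = DEFAULT_THRESHOLDS

    def cells(self) -> List[DemographicParams]:
        out = []
        for theta, rho, tau_d, frac, lam, (n1, n2) in itertools.product(
                self.theta, self.rho, self.tau_d, self.tau_m_fractions,
                self.lam, self.sample_configs):
            out.append(DemographicParams(
                theta=theta, rho=rho, tau_d=tau_d, tau_m=frac * tau_d,
                lam=lam, n1=n1, n2=n2))
        return out


def _cell_key(params: DemographicParams) -> str:
    return ("theta={theta}_rho={rho}_taud={tau_d}_taum={tau_m}"
            "_lam={lam}_n1={n1}_n2={n2}").format(**{
                k: getattr(params, k)
                for k in ("theta", "rho", "tau_d", "tau_m", "lam", "n1", "n2")})


def run_grid(
    grid: GridSpec,
    seed: int,
    checkpoint_dir: Optional[str | Path] = None,
    on_error: str = "record",
) -> List[SweepResult]:
    """Evaluate every grid cell; deterministic given ``seed``.

    Each cell gets a counter-derived seed, so results do not depend on
    evaluation order.  With ``checkpoint_dir`` set, completed cells are
    written as JSON and skipped on resume.  Per-cell failures are recorded
    (result replaced by ``None`` is avoided; the error is re-raised when
    ``on_error='raise'``).
    """
    cells = grid.cells()
    if not cells:
        raise ValueError("empty grid")
    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)
    results: List[SweepResult] = []
    for idx, params in enumerate(cells):
        cell_seed = int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))
        cache = ckpt / f"cell_{idx:05d}.json" if ckpt else None
        if cache and cache.exists():
            results.append(_result_from_json(json.loads(cache.read_text())))
            continue
        try:
            res = evaluate_batch(params, grid.n_windows, cell_seed, grid.thresholds)
        except Exception as exc:  # noqa: BLE001 - per-cell fault isolation
            if on_error == "raise":
                raise
            res = SweepResult(
                params=params, n_windows=grid.n_windows, n_defined=0,
                mean_gmin=math.nan, sd_gmin=math.nan,
                mean_fst=math.nan, sd_fst=math.nan, n_true_migrant=0)
        results.append(res)
        if cache:
            cache.write_text(json.dumps(_result_to_json(res)))
    return results


def _result_to_json(res: SweepResult) -> dict:
    d = {k: getattr(res.params, k)
         for k in ("theta", "rho", "tau_d", "tau_m", "lam", "n1", "n2")}
    out = {"params": d}
    for k in ("n_windows", "n_defined", "mean_gmin", "sd_gmin", "mean_fst",
              "sd_fst", "n_true_migrant"):
        out[k] = getattr(res, k)
    for k in ("n_called_gmin", "n_called_fst", "phi_gmin", "psi_gmin",
              "phi_fst", "psi_fst"):
        out[k] = {str(t): v for t, v in getattr(res, k).items()}
    return out


def _result_from_json(d: dict) -> SweepResult:
    params = DemographicParams(**d["params"])
    kw = {k: d[k] for k in ("n_windows", "n_defined", "mean_gmin", "sd_gmin",
                            "mean_fst", "sd_fst", "n_true_migrant")}
    for k in ("n_called_gmin", "n_called_fst"):
        kw[k] = {float(t): int(v) for t, v in d[k].items()}
    for k in ("phi_gmin", "psi_gmin", "phi_fst", "psi_fst"):
        kw[k] = {float(t): (math.nan if v is None else float(v))
                 for t, v in d[k].items()}
    return SweepResult(params=params, **kw)


def sweep_results_frame(results: Sequence[SweepResult]) -> pd.DataFrame:
    """Flatten SweepResults into a tidy table (one row per cell)."""
    rows = []
    for res in results:
        row = {k: getattr(res.params, k)
               for k in ("theta", "rho", "tau_d", "tau_m", "lam", "n1", "n2")}
        for k in ("n_windows", "n_defined", "mean_gmin", "sd_gmin",
                  "mean_fst", "sd_fst", "n_true_migrant"):
            row[k] = getattr(res, k)
        for stat in ("gmin", "fst"):
            for thr, v in getattr(res, f"n_called_{stat}").items():
                row[f"n_called_{stat}_{thr}"] = v
            for metric in ("phi", "psi"):
                for thr, v in getattr(res, f"{metric}_{stat}").items():
                    row[f"{metric}_{stat}_{thr}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

def variance_partition(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str] = ("tau_d", "theta", "rho", "n2"),
    interactions: Sequence[Tuple[str, str]] = (("tau_d", "n2"), ("tau_d", "rho")),
    all_pairwise: bool = False,
    min_percent: float = 0.0,
) -> pd.DataFrame:
    """Percent-of-total sum of squares per model term, plus residual.

    The cell-level response is regressed on centered numeric covariates for
    each factor and on products of centered covariates for each interaction.
    On a balanced full factorial these columns are mutually orthogonal, so
    the partition does not depend on term order; an unbalanced table is
    rejected.  ``all_pairwise=True`` replaces ``interactions`` with every
    factor pair.  Terms below ``min_percent`` can be suppressed from the
    output (the residual row is always kept).
    """
    # balance check: every factor combination appears equally often
    counts = table.groupby(list(factors), sort=False).size()
    if counts.nunique() != 1 or len(counts) != int(np.prod(
            [table[f].nunique() for f in factors])):
        raise ValueError(
            "variance_partition requires a balanced full-factorial table; "
            f"cell counts vary or cells are missing for factors {list(factors)}")

    y = table[response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"response {response!r} contains undefined values")
    y_c = y - y.mean()
    ss_total = float(y_c @ y_c)
    if ss_total == 0:
        raise ValueError(f"response {response!r} has zero variance")

    centered = {f: table[f].to_numpy(dtype=float) - table[f].to_numpy(dtype=float).mean()
                for f in factors}
    terms: List[Tuple[str, np.ndarray]] = [(f, centered[f]) for f in factors]
    pairs = (list(itertools.combinations(factors, 2))
             if all_pairwise else list(interactions))
    for a, b in pairs:
        terms.append((f"{a}:{b}", centered[a] * centered[b]))

    # orthogonality underwrites order invariance; verify rather than assume
    X = np.column_stack([c for _, c in terms])
    gram = X.T @ X
    off = gram - np.diag(np.diag(gram))
    scale = np.sqrt(np.outer(np.diag(gram), np.diag(gram)))
    if np.any(np.abs(off) > 1e-8 * np.maximum(scale, 1e-30)):
        raise ValueError(
            "design columns are not orthogonal; the partition would depend "
            "on term order (is the grid balanced and fully crossed?)")

    rows = []
    explained = 0.0
    for name, col in terms:
        denom = float(col @ col)
        ss = float((col @ y_c) ** 2 / denom) if denom > 0 else 0.0
        explained += ss
        rows.append({"term": name, "ss": ss, "percent": 100.0 * ss / ss_total})
    resid = ss_total - explained
    rows.append({"term": "residual", "ss": resid,
                 "percent": 100.0 * resid / ss_total})
    df = pd.DataFrame(rows)
    if min_percent > 0:
        keep = (df["percent"] >= min_percent) | (df["term"] == "residual")
        df = df[keep].reset_index(drop=True)
    return df
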