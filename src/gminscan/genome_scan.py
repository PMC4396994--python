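"""Sliding-window G_min / F_ST scans over phased haplotype alignments.

The scanner tiles a chromosome into non-overlapping windows (50 kb by
default), computes the haplotype-distance statistics in each window with
p-distances (pairwise deletion of missing data), drops windows where less
than a quarter of positions are callable, standardizes the remaining
values chromosome-wide, and flags outliers at Z < -1.645.  Windows can
also be rendered as neighbor-joining trees on the uncorrected p-distance
matrix for visual inspection of candidate introgressed haplotypes.

Input is either a multi-FASTA of equal-length haploid sequences or a
phased VCF (each diploid sample contributes two haplotype rows; haploid
calls contribute one), plus a two-column population map assigning every
sample to population 1 or 2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hapstats import (
    MISSING,
    HaplotypeWindow,
    UndefinedDistanceError,
    distance_summary,
    encode_sequences,
    fst_hudson,
    gmin,
    is_defined,
    pairwise_distance_matrix,
)
from .sweep_eval import zscores

__all__ = [
    "ScanConfig",
    "WindowStatRecord",
    "nj_tree",
    "read_haplotypes_fasta",
    "read_haplotypes_vcf",
    "read_population_map",
    "scan",
    "scan_records_frame",
    "write_scan_tsv",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters (defaults follow common whole-genome practice)."""

    window_size: int = 50_000
    min_callable_fraction: float = 0.25
    z_threshold: float = -1.645
    distance_mode: str = "p_distance"

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        if not (0 <= self.min_callable_fraction <= 1):
            raise ValueError("min_callable_fraction must be in [0, 1]")


@dataclass(frozen=True)
class WindowStatRecord:
    """Per-window scan output; coordinates are 0-based half-open."""

    chrom: str
    start: int
    end: int
    callable_fraction: float
    status: str  # ok | filtered | undefined
    gmin: float = math.nan
    fst: float = math.nan
    min_dxy: float = math.nan
    mean_dxy: float = math.nan
    mean_dxx: float = math.nan
    mean_dyy: float = math.nan
    z_gmin: float = math.nan
    z_fst: float = math.nan
    outlier_gmin: bool = False
    outlier_fst: bool = False
    is_short: bool = False


def read_population_map(path: str | Path) -> Dict[str, int]:
    """Two-column TSV: sample name, population label in {1, 2}."""
    popmap: Dict[str, int] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected two columns, got {len(parts)}")
        name, pop = parts
        if pop not in ("1", "2"):
            raise ValueError(f"{path}:{line_no}: population must be 1 or 2, got {pop!r}")
        popmap[name] = int(pop)
    if not popmap:
        raise ValueError(f"{path}: empty population map")
    return popmap


def _windows_over(chrom_length: int, window_size: int) -> Iterator[Tuple[int, int]]:
    """Exact tiling of [0, chrom_length); the last window may be short."""
    start = 0
    while start < chrom_length:
        yield start, min(start + window_size, chrom_length)
        start += window_size


def read_haplotypes_fasta(
    fasta_path: str | Path,
    popmap: Dict[str, int],
    window_size: int = 50_000,
    chrom: str = "chr",
) -> Iterator[HaplotypeWindow]:
    """Yield HaplotypeWindows tiling a multi-FASTA alignment.

    Every record is one haploid sequence; all must share one length.  A
    site is callable for a sequence when its state is an unambiguous base.
    """
    from Bio import SeqIO

    names: List[str] = []
    seqs: List[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq))
    if not names:
        raise ValueError(f"{fasta_path}: no FASTA records")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"{fasta_path}: FASTA records have unequal lengths {sorted(lengths)}")
    for name in names:
        if name not in popmap:
            raise KeyError(f"sample {name!r} missing from the population map")
    matrix = encode_sequences(seqs)
    labels = np.array([popmap[n] for n in names])
    chrom_length = lengths.pop()
    for start, end in _windows_over(chrom_length, window_size):
        yield HaplotypeWindow(
            matrix[:, start:end], labels,
            window_id=f"{chrom}:{start}-{end}",
            coords=(chrom, start, end),
            sample_names=tuple(names),
        )


def read_haplotypes_vcf(
    vcf_path: str | Path,
    popmap: Dict[str, int],
    window_size: int = 50_000,
    chrom: Optional[str] = None,
    chrom_length: Optional[int] = None,
) -> Iterator[HaplotypeWindow]:
    """Yield HaplotypeWindows from a phased VCF.

    Sites absent from the VCF are treated as monomorphic reference calls
    (callable for every haplotype); missing genotypes (./.) become missing
    states at that site only.  Diploid samples contribute two rows, haploid
    samples one.  ``chrom_length`` falls back to the ##contig header.
    """
    import pysam

    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    for name in samples:
        if name not in popmap:
            raise KeyError(f"sample {name!r} missing from the population map")

    if chrom is None:
        contigs = list(vf.header.contigs)
        if len(contigs) != 1:
            raise ValueError(
                "VCF declares multiple contigs; pass chrom= explicitly")
        chrom = contigs[0]
    if chrom_length is None:
        ctg = vf.header.contigs.get(chrom)
        if ctg is None or ctg.length is None:
            raise ValueError(
                f"no length declared for contig {chrom!r}; pass chrom_length=")
        chrom_length = ctg.length

    # determine row layout from the first record's ploidy per sample
    records = [rec for rec in vf.fetch() if rec.chrom == chrom] \
        if vf.index is not None else [rec for rec in vf if rec.chrom == chrom]
    row_names: List[str] = []
    row_labels: List[int] = []
    ploidy: Dict[str, int] = {}
    if records:
        first = records[0]
        for name in samples:
            ploidy[name] = len(first.samples[name]["GT"])
    else:
        ploidy = {name: 1 for name in samples}
    for name in samples:
        if ploidy[name] == 1:
            row_names.append(name)
            row_labels.append(popmap[name])
        else:
            for h in range(ploidy[name]):
                row_names.append(f"{name}_{h}")
                row_labels.append(popmap[name])
    n_rows = len(row_names)
    labels = np.array(row_labels)

    by_window: Dict[int, List[Tuple[int, np.ndarray]]] = {}
    for rec in records:
        pos0 = rec.pos - 1  # VCF is 1-based
        col = np.zeros(n_rows, dtype=np.int8)
        row = 0
        for name in samples:
            call = rec.samples[name]
            gt = call["GT"]
            phased = call.phased or len(gt) == 1
            if len(gt) > 1 and not phased and any(a is not None for a in gt):
                raise ValueError(
                    f"unphased genotype for sample {name!r} at {rec.chrom}:{rec.pos}")
            for allele in gt:
                col[row] = MISSING if allele is None else int(allele)
                row += 1
        by_window.setdefault(pos0 // window_size, []).append((pos0, col))

    for start, end in _windows_over(chrom_length, window_size):
        matrix = np.zeros((n_rows, end - start), dtype=np.int8)
        for pos0, col in by_window.get(start // window_size, []):
            if start <= pos0 < end:
                matrix[:, pos0 - start] = col
        yield HaplotypeWindow(
            matrix, labels,
            window_id=f"{chrom}:{start}-{end}",
            coords=(chrom, start, end),
            sample_names=tuple(row_names),
        )


def _callable_fraction(window: HaplotypeWindow) -> float:
    """Mean over sequences of the per-sequence callable-site fraction."""
    if window.n_sites == 0:
        return 0.0
    return float((window.sequences != MISSING).mean())


def scan(
    windows: Iterable[HaplotypeWindow],
    config: ScanConfig = ScanConfig(),
    window_size: Optional[int] = None,
) -> List[WindowStatRecord]:
    """Scan a window stream: statistics, chromosome-wide Z-scores, outliers."""
    wsize = window_size or config.window_size
    records: List[WindowStatRecord] = []
    for window in windows:
        chrom, start, end = window.coords if window.coords else ("chr", 0, window.n_sites)
        frac = _callable_fraction(window)
        base = dict(chrom=chrom, start=start, end=end, callable_fraction=frac,
                    is_short=(end - start) < wsize)
        if frac < config.min_callable_fraction:
            records.append(WindowStatRecord(status="filtered", **base))
            continue
        summ = distance_summary(window, mode=config.distance_mode)
        g = gmin(summ)
        f = fst_hudson(summ)
        status = "ok" if is_defined(g) else "undefined"
        records.append(WindowStatRecord(
            status=status, gmin=g, fst=f,
            min_dxy=summ.min_dxy, mean_dxy=summ.mean_dxy,
            mean_dxx=summ.mean_dxx, mean_dyy=summ.mean_dyy, **base))

    ok = [i for i, r in enumerate(records) if r.status == "ok"]
    if not ok:
        raise ValueError("no analyzable windows (all filtered or undefined)")
    zg = zscores([records[i].gmin for i in ok], batch_name="scan gmin")
    zf = zscores([records[i].fst for i in ok], batch_name="scan fst")
    for k, i in enumerate(ok):
        records[i] = replace(
            records[i],
            z_gmin=float(zg[k]), z_fst=float(zf[k]),
            outlier_gmin=bool(zg[k] < config.z_threshold),
            outlier_fst=bool(zf[k] < config.z_threshold),
        )
    return records


def scan_records_frame(records: Sequence[WindowStatRecord]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "callable_fraction", "status", "gmin",
            "fst", "min_dxy", "mean_dxy", "mean_dxx", "mean_dyy", "z_gmin",
            "z_fst", "outlier_gmin", "outlier_fst", "is_short"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def write_scan_tsv(records: Sequence[WindowStatRecord], path: str | Path) -> pd.DataFrame:
    """Write the per-window TSV (first three columns are BED-compatible)."""
    df = scan_records_frame(records)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
    return df


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(
    window: HaplotypeWindow,
    mode: str = "p_distance",
) -> str:
    """Neighbor-joining tree (Newick) on the window's p-distance matrix.

    Ties in the Q criterion are broken toward the lexicographically
    smallest joined pair; a negative branch length is clamped to zero with
    the deficit moved to its sister branch, preserving the pair distance.
    Consistent: additive distance matrices reproduce their generating tree.
    """
    names = list(window.names)
    if len(names) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    d = pairwise_distance_matrix(window.sequences, mode=mode, names=names)
    return neighbor_joining(d, names)


def neighbor_joining(d: np.ndarray, names: Sequence[str]) -> str:
    """Classic NJ agglomeration on a symmetric distance matrix -> Newick."""
    d = np.array(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(names):
        raise ValueError("distance matrix and name list are inconsistent")
    nodes = [f"{name}" for name in names]
    # 'labels' orders tie-breaking; follow the original leaf names
    keys = [str(name) for name in names]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((i, j) for i, j in ties if i < j),
            key=lambda ij: tuple(sorted((keys[active[ij[0]]], keys[active[ij[1]]]))),
        )
        i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        # distances from the new node u to every other active node
        du = 0.5 * (d[ai, :] + d[aj, :] - dij)
        new = f"({nodes[ai]}:{li:.10g},{nodes[aj]}:{lj:.10g})"
        newkey = min(keys[ai], keys[aj])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = du
        d[:-1, -1] = du
        d[-1, -1] = 0.0
        nodes.append(new)
        keys.append(newkey)
        active = [a for a in active if a not in (ai, aj)] + [d.shape[0] - 1]

    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
        lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
        lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
        return (f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},"
                f"{nodes[c]}:{lc:.10g});")
    # exactly two nodes left
    a, b = active
    return f"({nodes[a]}:{d[a, b] / 2:.10g},{nodes[b]}:{d[a, b] / 2:.10g});"
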