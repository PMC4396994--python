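"""Tests for the window scanner, format readers and neighbor joining."""

import math

import numpy as np
import pytest

from gminscan.coalsim import DemographicParams, simulate_batch
from gminscan.genome_scan import (
    ScanConfig,
    WindowStatRecord,
    _windows_over,
    neighbor_joining,
    nj_tree,
    read_haplotypes_fasta,
    read_haplotypes_vcf,
    read_population_map,
    scan,
    scan_records_frame,
    write_scan_tsv,
)
from gminscan.hapstats import MISSING, HaplotypeWindow, distance_summary, gmin


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def write_fasta(path, names, seqs):
    with open(path, "w") as fh:
        for name, seq in zip(names, seqs):
            fh.write(f">{name}\n{seq}\n")


def parse_newick_distances(newick):
    """Leaf-to-leaf path lengths via skbio (oracle-side parsing)."""
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


# ---------------------------------------------------------------------------
# tiling and IO
# ---------------------------------------------------------------------------

def test_window_tiling_exact():
    windows = list(_windows_over(1_000_000, 50_000))
    assert len(windows) == 20
    assert windows[0] == (0, 50_000) and windows[-1] == (950_000, 1_000_000)
    # disjoint union covers the chromosome; a short tail is kept
    tail = list(_windows_over(120_001, 50_000))
    assert tail[-1] == (100_000, 120_001)
    spans = sum(e - s for s, e in tail)
    assert spans == 120_001


def test_fasta_reader_and_popmap(tmp_path):
    fasta = tmp_path / "toy.fasta"
    write_fasta(fasta, ["a1", "a2", "b1"], ["ACGTACGTAC", "ACGTACGTAC", "TTTTACGTAC"])
    popmap = tmp_path / "pops.tsv"
    popmap.write_text("a1\t1\na2\t1\nb1\t2\n")
    pm = read_population_map(popmap)
    wins = list(read_haplotypes_fasta(fasta, pm, window_size=4))
    assert len(wins) == 3
    assert wins[0].coords == ("chr", 0, 4)
    assert wins[-1].coords == ("chr", 8, 10)
    assert wins[0].n1 == 2 and wins[0].n2 == 1
    # first window ACGT vs TTTT: differences at the three non-T sites
    s = distance_summary(wins[0], mode="count")
    assert s.mean_dxy == 3.0


def test_fasta_reader_rejects_unequal_lengths_and_unmapped_samples(tmp_path):
    fasta = tmp_path / "bad.fasta"
    write_fasta(fasta, ["a1", "b1"], ["ACGT", "ACG"])
    popmap = {"a1": 1, "b1": 2}
    with pytest.raises(ValueError, match="unequal"):
        list(read_haplotypes_fasta(fasta, popmap))
    write_fasta(fasta, ["a1", "bX"], ["ACGT", "ACGT"])
    with pytest.raises(KeyError, match="bX"):
        list(read_haplotypes_fasta(fasta, popmap))


def test_vcf_reader_missing_and_phased(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text("\n".join([
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=12>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampA\tsampB",
        "chr1\t3\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1",
        "chr1\t7\t.\tA\tT\t.\tPASS\t.\tGT\t./.\t0|0",
    ]) + "\n")
    pm = {"sampA": 1, "sampB": 2}
    wins = list(read_haplotypes_vcf(vcf, pm, window_size=12))
    assert len(wins) == 1
    w = wins[0]
    assert w.sequences.shape == (4, 12)  # two diploid samples -> 4 haplotypes
    # position 3 (0-based 2): alleles 0,1,1,1
    assert list(w.sequences[:, 2]) == [0, 1, 1, 1]
    # the ./. genotype marks missing states for sampA's two rows at site 7 only
    assert list(w.sequences[:2, 6]) == [MISSING, MISSING]
    assert (w.sequences[:2, :6] != MISSING).all()
    # all other positions are monomorphic callable reference
    assert (w.sequences[:, 0] == 0).all()


def test_vcf_reader_rejects_unphased(tmp_path):
    vcf = tmp_path / "unphased.vcf"
    vcf.write_text("\n".join([
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=10>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1",
        "chr1\t2\t.\tA\tT\t.\tPASS\t.\tGT\t0/1",
    ]) + "\n")
    with pytest.raises(ValueError, match="unphased"):
        list(read_haplotypes_vcf(vcf, {"s1": 1}, window_size=10))


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def _sim_to_strings(sim, window_size):
    """Render a simulated window as fixed-length nucleotide strings."""
    n, s = sim.window.sequences.shape
    base = np.full((n, window_size), "A", dtype="U1")
    used = set()
    for col, pos in enumerate(sim.positions):
        off = int(pos * window_size)
        while off in used and off < window_size - 1:
            off += 1
        if off in used:
            continue
        used.add(off)
        derived = sim.window.sequences[:, col] == 1
        base[derived, off] = "T"
    return ["".join(row) for row in base]


def test_scan_matches_direct_statistics(tmp_path):
    """No format-layer drift: scanning a FASTA reproduces hapstats values."""
    params = DemographicParams(theta=30, rho=0, tau_d=1.0, n1=4, n2=4)
    sims = simulate_batch(params, 6, seed=17)
    wsize = 500
    seqs = ["".join(parts) for parts in zip(
        *[_sim_to_strings(s, wsize) for s in sims])]
    names = [f"p1_{i}" for i in range(4)] + [f"p2_{i}" for i in range(4)]
    fasta = tmp_path / "chr.fasta"
    write_fasta(fasta, names, seqs)
    pm = {n: (1 if n.startswith("p1") else 2) for n in names}
    wins = list(read_haplotypes_fasta(fasta, pm, window_size=wsize))
    records = scan(wins, ScanConfig(window_size=wsize))
    assert len(records) == 6
    for rec, w in zip(records, wins):
        direct = gmin(distance_summary(w, mode="p_distance"))
        if math.isnan(direct):
            assert rec.status == "undefined"
        else:
            assert rec.gmin == pytest.approx(direct)


def test_scan_filters_low_callable_windows():
    seqs = np.zeros((4, 300), dtype=np.int8)
    seqs[0, 10] = 1   # polymorphism in windows 0 and 2 so Z-scores exist
    seqs[2, 50] = 1
    seqs[3, 220] = 1
    seqs[0, 250] = 1
    seqs[1, 250] = 1  # distinct G_min values across ok windows
    labels = np.array([1, 1, 2, 2])
    windows = []
    for i, (s, e) in enumerate([(0, 100), (100, 200), (200, 300)]):
        sub = seqs[:, s:e].copy()
        if i == 1:
            sub[:, :80] = MISSING  # 20% callable -> filtered
        windows.append(HaplotypeWindow(sub, labels, coords=("c", s, e)))
    records = scan(windows, ScanConfig(window_size=100, min_callable_fraction=0.25))
    assert records[1].status == "filtered"
    assert records[1].callable_fraction == pytest.approx(0.2)
    assert math.isnan(records[1].z_gmin) and not records[1].outlier_gmin
    assert records[0].status == "ok" and records[2].status == "ok"


def test_scan_requires_analyzable_windows():
    seqs = np.full((4, 50), MISSING, dtype=np.int8)
    labels = np.array([1, 1, 2, 2])
    windows = [HaplotypeWindow(seqs, labels, coords=("c", 0, 50))]
    with pytest.raises(ValueError, match="no analyzable windows"):
        scan(windows, ScanConfig(window_size=50))


def test_scan_deterministic_tsv(tmp_path):
    params = DemographicParams(theta=30, rho=0, tau_d=1.0, n1=4, n2=4)
    sims = simulate_batch(params, 8, seed=18)
    wsize = 400
    seqs = ["".join(parts) for parts in zip(
        *[_sim_to_strings(s, wsize) for s in sims])]
    names = [f"s{i}" for i in range(8)]
    fasta = tmp_path / "c.fasta"
    write_fasta(fasta, names, seqs)
    pm = {n: (1 if i < 4 else 2) for i, n in enumerate(names)}
    out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    for out in (out1, out2):
        wins = list(read_haplotypes_fasta(fasta, pm, window_size=wsize))
        write_scan_tsv(scan(wins, ScanConfig(window_size=wsize)), out)
    assert out1.read_bytes() == out2.read_bytes()


def test_injected_migrant_windows_rank_lowest(tmp_path):
    """Pulse-affected windows sit in the lowest G_min Z-scores of a scan."""
    from gminscan.cli_io import make_fixtures
    import json

    paths = make_fixtures(tmp_path, seed=5, window_size=5000, n_windows=45)
    pm = read_population_map(paths["popmap"])
    wins = list(read_haplotypes_fasta(paths["fasta"], pm, window_size=5000,
                                      chrom="chrS"))
    records = scan(wins, ScanConfig(window_size=5000))
    truth = json.load(open(paths["truth"]))
    injected = {t["window"] for t in truth["migrant_windows"]}
    df = scan_records_frame(records)
    ranked = df["z_gmin"].rank()
    mean_rank_injected = ranked[sorted(injected)].mean()
    mean_rank_rest = ranked.drop(index=sorted(injected)).mean()
    assert mean_rank_injected < mean_rank_rest
    assert df.loc[sorted(injected), "outlier_gmin"].any()


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxa_closed_form():
    d = np.array([[0, 3, 4],
                  [3, 0, 5],
                  [4, 5, 0]], dtype=float)
    newick = neighbor_joining(d, ["A", "B", "C"])
    dist = parse_newick_distances(newick)
    # closed form: la = (dab+dac-dbc)/2 = 1, lb = 2, lc = 3
    assert dist[("A", "B")] == pytest.approx(3)
    assert dist[("A", "C")] == pytest.approx(4)
    assert dist[("B", "C")] == pytest.approx(5)


def test_nj_recovers_hand_built_additive_tree():
    # tree: ((A:1,B:2):1,C:3,D:4) with internal edge 1
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0]], dtype=float)
    newick = neighbor_joining(d, ["A", "B", "C", "D"])
    dist = parse_newick_distances(newick)
    for (a, b), expected in {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
                             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}.items():
        assert dist[(a, b)] == pytest.approx(expected, abs=1e-9)


def test_nj_consistent_on_random_additive_matrices(rng):
    """NJ reproduces path lengths of random trees (n <= 8), matching the
    skbio implementation used as an independent oracle."""
    import io

    import skbio

    for trial in range(10):
        n = int(rng.integers(4, 9))
        names = [f"t{i}" for i in range(n)]
        # random additive tree: random sequential joins, positive lengths
        nodes = {name: name for name in names}
        dist = {}
        import itertools as it

        # build tree bottom-up; track patristic distances exactly
        depth = {name: 0.0 for name in names}
        members = [[name] for name in names]
        paths = {}
        while len(members) > 1:
            i, j = sorted(rng.choice(len(members), size=2, replace=False))
            li, lj = rng.uniform(0.1, 2.0, 2)
            for a in members[i]:
                depth[a] += li
            for b in members[j]:
                depth[b] += lj
            for a in members[i]:
                for b in members[j]:
                    paths[tuple(sorted((a, b)))] = depth[a] + depth[b]
            members[i] = members[i] + members[j]
            del members[j]
        d = np.zeros((n, n))
        for (a, b), v in paths.items():
            ia, ib = names.index(a), names.index(b)
            d[ia, ib] = d[ib, ia] = v
        newick = neighbor_joining(d, names)
        got = parse_newick_distances(newick)
        for (a, b), v in paths.items():
            assert got[(a, b)] == pytest.approx(v, abs=1e-8)
        # oracle agreement: skbio's NJ must induce the same path lengths
        dm = skbio.DistanceMatrix(d, ids=names)
        sk = skbio.tree.nj(dm)
        for (a, b), v in paths.items():
            assert sk.find(a).distance(sk.find(b)) == pytest.approx(v, abs=1e-8)


def test_nj_migrant_nests_inside_source_clade():
    """A haplotype nearly identical to population-2 sequences attaches
    within the population-2 part of the tree."""
    import io

    from skbio import TreeNode

    pop1 = ["AAAAAAAAAA"] * 3 + ["TTTTTTTTTA"]  # last one is the migrant
    pop2 = ["TTTTTTTTTT", "TTTTTTTTGT", "TTTTTTTCTT"]
    w = HaplotypeWindow.from_strings(pop1, pop2)
    newick = nj_tree(w)
    tree = TreeNode.read(io.StringIO(newick))
    migrant = tree.find("h3")
    # patristic distances: the migrant is nearer every source-population tip
    # than any tip of its labelled population
    to_pop2 = max(migrant.distance(tree.find(t)) for t in ("h4", "h5", "h6"))
    to_pop1 = min(migrant.distance(tree.find(t)) for t in ("h0", "h1", "h2"))
    assert to_pop2 < to_pop1
    # and an internal edge separates {migrant + pop2} from pop1
    for node in tree.non_tips(include_self=True):
        tips = {t.name for t in node.tips()}
        if tips == {"h3", "h4", "h5", "h6"} or tips == {"h0", "h1", "h2"}:
            break
    else:
        pytest.fail("no bipartition grouping the migrant with population 2")


def test_nj_requires_three_sequences():
    w = HaplotypeWindow.from_strings(["00"], ["01"])
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(w)
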