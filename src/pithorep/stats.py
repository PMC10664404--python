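"""Statistics on genes inside vs outside repeat-rich regions.

Covers: interval intersection of genes with regions (midpoint rule),
chi-square enrichment tests, the Cochran-Armitage trend test of gene
ancestry vs repeat residency, a Nei-Gojobori (NG86) counting estimator
of dN/dS with Jukes-Cantor correction, masked-genome metrics,
modified-base (IPD ratio) density comparison, and a Kolmogorov-Smirnov
test of repeat placement uniformity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats as sps

from .genome import CircularGenome, gc_fraction

# codon -> amino acid (stop = '*'), standard genetic code
CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_AA[_stop] = "*"


@dataclass
class ContingencyResult:
    table: np.ndarray
    statistic: float
    p_value: float
    test: str  # chi2 | cochran_armitage | wilcoxon | ks
    extra: dict | None = None


# ---------------------------------------------------------------------------
# gene/region intersection


def genes_in_regions(genes: pd.DataFrame, regions: pd.DataFrame,
                     rule: str = "midpoint") -> pd.DataFrame:
    """Flag genes lying within repeat-rich regions.

    ``rule='midpoint'`` (default) counts a gene as inside when its
    midpoint falls in a region, so every gene lands on exactly one side;
    ``rule='overlap'`` uses any-overlap (bedtools-intersect style).
    Region and gene tables must refer to the same genome(s).
    """
    out = genes.copy()
    gnames = set(out["genome"].unique())
    rcol = "chrom" if "chrom" in regions.columns else "genome"
    rnames = set(regions[rcol].unique()) if len(regions) else set()
    if len(regions) and not rnames & gnames:
        raise ValueError(f"genome ids of genes {sorted(gnames)} and regions "
                         f"{sorted(rnames)} do not overlap")
    flags = np.zeros(len(out), dtype=bool)
    for gname in gnames:
        sel = (out["genome"] == gname).to_numpy()
        sub = regions[regions[rcol] == gname] if len(regions) else regions
        if not len(sub):
            continue
        rs = sub["start"].to_numpy()
        re_ = sub["end"].to_numpy()
        gs = out.loc[sel, "start"].to_numpy()
        ge = out.loc[sel, "end"].to_numpy()
        if rule == "midpoint":
            mid = (gs + ge) // 2
            flags[sel] = [(bool(np.any((rs <= m) & (m < re_)))) for m in mid]
        elif rule == "overlap":
            flags[sel] = [bool(np.any((s < re_) & (e > rs))) for s, e in zip(gs, ge)]
        else:
            raise ValueError(f"unknown rule {rule!r}")
    out["in_repeat"] = flags
    return out


def enrichment_chi2(in_counts: tuple[int, int], out_counts: tuple[int, int],
                    correction: bool = False) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table of (hits, totals) inside vs outside.

    ``in_counts`` = (k_in, n_in): e.g. HGT genes and total genes within
    repeat regions; same for outside.  No continuity correction by
    default.
    """
    k_in, n_in = in_counts
    k_out, n_out = out_counts
    if n_in <= 0 or n_out <= 0:
        raise ValueError("totals must be positive")
    table = np.array([[k_in, n_in - k_in], [k_out, n_out - k_out]])
    if (table < 0).any():
        raise ValueError("hits exceed totals")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table with a zero margin")
    if (table == table[0]).all():  # identical rows: statistic exactly 0
        return ContingencyResult(table, 0.0, 1.0, "chi2")
    stat, p, _dof, _exp = sps.chi2_contingency(table, correction=correction)
    return ContingencyResult(table, float(stat), float(p), "chi2")


# ---------------------------------------------------------------------------
# ancestry trend


def cochran_armitage(successes: np.ndarray, totals: np.ndarray,
                     scores: np.ndarray | None = None) -> ContingencyResult:
    """Cochran-Armitage test for a trend in proportions across ordered groups.

    Groups are ordered (here: ancestry nodes from most ancient to most
    recent) with integer scores 0..k-1 by default; the two-sided p-value
    comes from the normal approximation of the score statistic.
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if scores is None:
        scores = np.arange(len(x), dtype=float)
    s = np.asarray(scores, dtype=float)
    N = n.sum()
    phat = x.sum() / N
    T = float(np.sum(s * (x - n * phat)))
    var = phat * (1 - phat) * (np.sum(s**2 * n) - np.sum(s * n) ** 2 / N)
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = T / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    table = np.array([x, n - x])
    return ContingencyResult(table, float(z), float(p), "cochran_armitage")


def ancestry_order(tree, focal_leaf: str) -> list:
    """Clades on the root-to-leaf path of the focal genome, ancient first."""
    path = tree.get_path(focal_leaf)
    return [tree.root] + list(path)


def assign_ancestry(tree, hog_genomes: list[str], focal_leaf: str):
    """Last common ancestor of the genomes carrying a HOG (incl. the focal).

    A HOG spanning all leaves maps to the root; a singleton maps to the
    focal leaf itself.
    """
    names = set(hog_genomes) | {focal_leaf}
    if len(names) == 1:
        return next(tree.find_clades(name=focal_leaf))
    return tree.common_ancestor(sorted(names))


def ancestry_trend(genes: pd.DataFrame, node_order: list) -> ContingencyResult:
    """Trend of in-repeat gene fraction across ordered ancestry nodes.

    ``genes`` needs columns ``ancestry_node`` and ``in_repeat``;
    ``node_order`` lists node identifiers from most ancient to most
    recent.  Genes at nodes missing from the order raise an error.
    """
    nodes = list(node_order)
    unknown = set(genes["ancestry_node"]) - set(nodes)
    if unknown:
        raise ValueError(f"genes at nodes outside the given order: {sorted(map(str, unknown))}")
    x, n = [], []
    for node in nodes:
        sub = genes[genes["ancestry_node"] == node]
        x.append(int(sub["in_repeat"].sum()))
        n.append(len(sub))
    keep = [i for i, t in enumerate(n) if t > 0]
    return cochran_armitage(np.array(x)[keep], np.array(n)[keep],
                            scores=np.array(keep, dtype=float))


# ---------------------------------------------------------------------------
# NG86 dN/dS


@dataclass
class DnDsEstimate:
    dn: float
    ds: float
    omega: float
    accepted: bool
    n_syn_sites: float
    n_nonsyn_sites: float


def _syn_fractions() -> dict[str, tuple[float, float]]:
    """Synonymous/nonsynonymous site counts per codon (NG86 convention:
    each position contributes 1 site split by the fraction of its three
    single-base neighbors that are synonymous; mutations to stop codons
    count as nonsynonymous)."""
    out = {}
    for codon, aa in CODON_AA.items():
        if aa == "*":
            continue
        S = 0.0
        for pos in range(3):
            syn = sum(
                1
                for b in "ACGT"
                if b != codon[pos]
                and CODON_AA[codon[:pos] + b + codon[pos + 1:]] == aa
            )
            S += syn / 3.0
        out[codon] = (S, 3.0 - S)
    return out


_SYN_SITES = _syn_fractions()


def _path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Mean synonymous/nonsynonymous differences over all shortest
    mutational paths between two codons.  A step is synonymous when it
    preserves the encoded amino acid; steps into stop codons count as
    nonsynonymous (the convention of the reference NG86 counting
    implementations)."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in permutations(pos):
        cur = c1
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            aa_cur, aa_nxt = CODON_AA[cur], CODON_AA[nxt]
            if aa_cur == aa_nxt and aa_nxt != "*":
                sd_total += 1
            elif aa_cur == aa_nxt == "*":
                sd_total += 1
            else:
                nd_total += 1
            cur = nxt
        n_paths += 1
    return sd_total / n_paths, nd_total / n_paths


def _jukes_cantor(p: float) -> float:
    if p <= 0:
        return 0.0
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(cds_a: str, cds_b: str, ds_min: float = 0.1, ds_max: float = 1.5,
              omega_max: float = 10.0) -> DnDsEstimate:
    """Nei-Gojobori counting estimate of dN and dS for an aligned CDS pair.

    Synonymous/nonsynonymous site counts are averaged over the two
    sequences; differences are averaged over all shortest codon paths;
    proportions are Jukes-Cantor corrected.  ``accepted`` applies the
    standard quality filters ds_min < dS < ds_max and dN/dS < omega_max
    used before averaging ratios over gene pairs.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS pair must have equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for p in range(0, len(cds_a), 3):
        ca, cb = cds_a[p : p + 3], cds_b[p : p + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if CODON_AA.get(ca) == "*" or CODON_AA.get(cb) == "*":
            raise ValueError(f"internal stop codon at position {p}")
        sa, na = _SYN_SITES[ca]
        sb, nb = _SYN_SITES[cb]
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _path_diffs(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons")
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    omega = dn / ds if ds > 0 else float("nan")
    accepted = (ds_min < ds < ds_max) and (not math.isnan(omega)) and omega < omega_max
    return DnDsEstimate(dn=dn, ds=ds, omega=omega, accepted=accepted,
                        n_syn_sites=S, n_nonsyn_sites=N)


def compare_dnds(values_in: pd.DataFrame, values_out: pd.DataFrame
                 ) -> dict[str, ContingencyResult]:
    """Wilcoxon rank-sum comparison of per-gene dn/ds/omega in vs out.

    Inputs are per-gene tables (means over qualifying ortholog pairs)
    with columns ``dn``, ``ds``, ``omega``; each metric is tested
    independently, two-sided.
    """
    out = {}
    for metric in ("dn", "ds", "omega"):
        a = values_in[metric].dropna().to_numpy()
        b = values_out[metric].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >=2 values per side for {metric}")
        stat, p = sps.ranksums(a, b)
        out[metric] = ContingencyResult(
            np.array([[len(a)], [len(b)]]), float(stat), float(p), "wilcoxon",
            extra={"median_in": float(np.median(a)), "median_out": float(np.median(b))},
        )
    return out


# ---------------------------------------------------------------------------
# masked-genome metrics


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _coverage_fraction(intervals: list[tuple[int, int]], within: list[tuple[int, int]]) -> float:
    """Fraction of the (merged) ``within`` intervals covered by ``intervals``."""
    total = sum(e - s for s, e in within)
    if total == 0:
        return 0.0
    cov = 0
    merged = _merge_intervals(intervals)
    for ws, we in within:
        for s, e in merged:
            lo, hi = max(s, ws), min(e, we)
            if hi > lo:
                cov += hi - lo
    return cov / total


def masked_metrics(genome: CircularGenome, regions: pd.DataFrame,
                   genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Length, GC% and coding density with and without repeat regions.

    Returns a two-row frame indexed ``real`` / ``masked``; the masked
    row is computed on the complement of the (merged) repeat-rich
    regions.
    """
    L = len(genome)
    reg = _merge_intervals([(int(s), int(e)) for s, e in
                            zip(regions.get("start", []), regions.get("end", []))])
    for s, e in reg:
        if s < 0 or e > L:
            raise IndexError(f"region [{s}, {e}) outside genome of length {L}")
    complement = []
    pos = 0
    for s, e in reg:
        if s > pos:
            complement.append((pos, s))
        pos = max(pos, e)
    if pos < L:
        complement.append((pos, L))
    if not reg:
        complement = [(0, L)]
    gene_iv = ([(int(s), int(e)) for s, e in zip(genes["start"], genes["end"])]
               if genes is not None and len(genes) else [])
    masked_seq = "".join(genome.seq[s:e] for s, e in complement)
    rows = {
        "real": {
            "length_kb": L / 1000.0,
            "gc_pct": 100.0 * gc_fraction(genome.seq),
            "coding_density": _coverage_fraction(gene_iv, [(0, L)]),
        },
        "masked": {
            "length_kb": len(masked_seq) / 1000.0,
            "gc_pct": 100.0 * gc_fraction(masked_seq) if masked_seq else float("nan"),
            "coding_density": _coverage_fraction(gene_iv, complement),
        },
    }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# modified bases


def modified_base_density(track: pd.DataFrame, halves: list[tuple[int, int]],
                          threshold: float = 4.5) -> ContingencyResult:
    """Compare putatively modified base density between two genome intervals.

    Positions with IPD ratio above ``threshold`` count as modified; the
    2x2 chi-square contrasts modified vs unmodified covered positions in
    the two intervals.  Densities per kb are reported alongside.
    """
    if len(halves) != 2:
        raise ValueError("exactly two intervals required")
    counts = []
    for s, e in halves:
        if e <= s:
            raise ValueError(f"empty interval [{s}, {e})")
        sub = track[(track["position"] >= s) & (track["position"] < e)]
        mod = int((sub["ipd_ratio"] > threshold).sum())
        counts.append((mod, len(sub)))
    table = np.array([[m, n - m] for m, n in counts])
    dens = {f"density_per_kb_{i}": 1000.0 * m / n if n else float("nan")
            for i, (m, n) in enumerate(counts)}
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: an interval has no coverage "
                         "or no (un)modified positions overall")
    if (table == table[0]).all():
        return ContingencyResult(table, 0.0, 1.0, "chi2", extra=dens)
    stat, p, _dof, _exp = sps.chi2_contingency(table, correction=False)
    return ContingencyResult(table, float(stat), float(p), "chi2", extra=dens)


# ---------------------------------------------------------------------------
# repeat placement uniformity


def repeat_uniformity(regions: pd.DataFrame, genome_length: int,
                      min_regions: int = 5) -> ContingencyResult:
    """One-sample KS test of region midpoints against Uniform(0, L)."""
    if len(regions) < min_regions:
        raise ValueError(f"need at least {min_regions} regions")
    mids = ((regions["start"] + regions["end"]) / 2.0) / genome_length
    stat, p = sps.kstest(np.sort(mids), "uniform")
    return ContingencyResult(np.array([[len(regions)]]), float(stat), float(p), "ks")


# ---------------------------------------------------------------------------
# conservative/creative halves


def halves_by_core_density(gene_mids: np.ndarray, core_flags: np.ndarray,
                           genome_length: int, window: int = 21
                           ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split the circle into two arcs at the core-density extremes.

    Returns (conservative, creative) interval lists: the arc running
    from the density minimum to the maximum gene (exclusive of wrap) and
    its complement.  Wrapping arcs are returned as two pieces.
    """
    from .pangenome import core_density_window

    dens = core_density_window(np.asarray(core_flags, dtype=float), window=window)
    hi = int(gene_mids[int(np.argmax(dens))])
    lo = int(gene_mids[int(np.argmin(dens))])

    def arc(a: int, b: int) -> list[tuple[int, int]]:
        if a == b:
            return [(0, genome_length)]
        if a < b:
            return [(a, b)]
        return [(a, genome_length), (0, b)]

    return arc(lo, hi), arc(hi, lo)
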