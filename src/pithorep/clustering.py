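"""Repeat clustering, M1/M2 labeling, region grammar, TSD/TIR detection.

Repeat units are clustered greedily: units are ordered by their mean
distance (100 - global identity %) to their 10 nearest neighbors; the
first unit becomes a reference, and each subsequent unit joins the first
reference it matches at >= 70% identity or founds a new cluster.
Clusters whose member sets are mutually >= 70% identical to each
other's reference (in more than half of members, both directions) are
merged.  The two largest clusters are labeled M1 and M2 -- the two
palindromic MITE-like families that colonize pithovirus genomes -- and
regions are validated against the (M1-M2){n}-M1 grammar.

Global identities follow the EMBOSS needle convention: Needleman-
Wunsch with match +5 / mismatch -4, affine gaps 10/0.5, free end gaps;
identity = matches / alignment columns (end gaps included).  An
edit-distance backend (edlib) computing the same matches-over-columns
ratio under unit costs is available for large unit sets; at the
divergences relevant near the 70% threshold the two agree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align
from scipy.stats import ranksums

from .detection import RepeatUnit
from .genome import CircularGenome, revcomp


def _needle_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 5.0
    al.mismatch_score = -4.0
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    al.end_gap_score = 0.0  # needle does not penalize end gaps by default
    return al


_ALIGNER = _needle_aligner()
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def global_identity(a: str, b: str, backend: str = "needle") -> float:
    """Percent identity of the global alignment of two DNA strings.

    Identity is matches divided by alignment columns (end gaps counted)
    times 100.  ``backend='edlib'`` uses the unit-cost edit-distance
    alignment instead of needle scoring.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    if backend == "needle":
        aln = _ALIGNER.align(a, b)[0]
        counts = aln.counts()
        return 100.0 * counts.identities / aln.length
    if backend == "edlib":
        res = edlib.align(a, b, mode="NW", task="path")
        cols = sum(int(n) for n, _op in _CIGAR_RE.findall(res["cigar"]))
        return 100.0 * (cols - res["editDistance"]) / cols
    raise ValueError(f"unknown identity backend {backend!r}")


def identity_matrix(seqs: list[str], backend: str = "auto",
                    needle_max_n: int = 200) -> np.ndarray:
    """Symmetric n x n matrix of pairwise global identities (diagonal 100).

    ``backend='auto'`` uses needle up to ``needle_max_n`` sequences and
    the edit-distance backend beyond that.
    """
    n = len(seqs)
    if backend == "auto":
        backend = "needle" if n <= needle_max_n else "edlib"
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = global_identity(seqs[i], seqs[j], backend=backend)
    return mat


@dataclass
class RepeatCluster:
    cluster_id: int
    reference: int            # index of the reference unit
    members: list[int]        # unit indices, reference included
    label: str = "unlabeled"  # M1 | M2 | M1-like | M2-like | unlabeled

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Clustering:
    """Units, their pairwise identity matrix and the cluster partition."""

    units: list[RepeatUnit]
    identity: np.ndarray
    clusters: list[RepeatCluster]

    def labels(self) -> list[str]:
        out = ["unlabeled"] * len(self.units)
        for c in self.clusters:
            for m in c.members:
                out[m] = c.label
        return out

    def cluster_of(self) -> np.ndarray:
        out = np.full(len(self.units), -1)
        for c in self.clusters:
            out[c.members] = c.cluster_id
        return out


def _processing_order(identity: np.ndarray, units: list[RepeatUnit],
                      knn: int = 10) -> list[int]:
    """Ascending mean distance to the k nearest neighbors; coordinate ties."""
    n = len(units)
    dist = 100.0 - identity
    order_keys = []
    for i in range(n):
        others = np.delete(dist[i], i)
        k = min(knn, len(others))
        mean_d = float(np.sort(others)[:k].mean()) if k else 0.0
        order_keys.append((mean_d, units[i].start, units[i].end, i))
    return [t[3] for t in sorted(order_keys)]


def greedy_cluster(units: list[RepeatUnit], threshold: float = 70.0,
                   knn: int = 10, identity: np.ndarray | None = None,
                   backend: str = "auto") -> Clustering:
    """Greedy reference-based clustering of repeat units.

    Deterministic: the processing order is the mean-distance sort with
    genomic-coordinate tie-breaks, and each unit joins the *first*
    existing reference it matches at >= threshold identity.
    """
    if not units:
        raise ValueError("no units to cluster")
    if identity is None:
        identity = identity_matrix([u.seq for u in units], backend=backend)
    order = _processing_order(identity, units, knn=knn)
    clusters: list[RepeatCluster] = []
    for idx in order:
        for c in clusters:
            if identity[idx, c.reference] >= threshold:
                c.members.append(idx)
                break
        else:
            clusters.append(RepeatCluster(cluster_id=len(clusters),
                                          reference=idx, members=[idx]))
    for c in clusters:
        c.members.sort()
    return Clustering(units=units, identity=identity, clusters=clusters)


def merge_clusters(clustering: Clustering, threshold: float = 70.0) -> Clustering:
    """Merge clusters whose member sets cross-match each other's reference.

    Two clusters merge when more than half of each cluster's members are
    >= threshold identical to the other cluster's reference; merging is
    closed transitively and the merged cluster keeps the reference of
    its largest constituent.  Idempotent.
    """
    clusters = clustering.clusters
    ident = clustering.identity
    n = len(clusters)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = clusters[i], clusters[j]
            frac_a = np.mean(ident[a.members, b.reference] >= threshold)
            frac_b = np.mean(ident[b.members, a.reference] >= threshold)
            if frac_a > 0.5 and frac_b > 0.5:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members_idx in groups.values():
        parts = sorted((clusters[i] for i in members_idx),
                       key=lambda c: (-c.size, c.cluster_id))
        all_members = sorted({m for c in parts for m in c.members})
        merged.append(RepeatCluster(cluster_id=0, reference=parts[0].reference,
                                    members=all_members))
    merged.sort(key=lambda c: min(c.members))
    for k, c in enumerate(merged):
        c.cluster_id = k
    return Clustering(units=clustering.units, identity=ident, clusters=merged)


def label_m1_m2(clustering: Clustering, references: dict[str, str] | None = None,
                threshold: float = 70.0, backend: str = "needle") -> Clustering:
    """Label clusters M1/M2 by size rank, or by supplied reference sequences.

    Without external references the largest cluster is M1 and the second
    largest M2 (M1 is the more abundant family); smaller clusters whose
    reference aligns to the M1 (M2) reference at >= threshold become
    "M1-like" ("M2-like").  With a reference FASTA mapping, each cluster
    takes the name of its best-matching reference when that match
    reaches the threshold.
    """
    clusters = clustering.clusters
    units = clustering.units
    if not clusters:
        return clustering
    if references:
        for c in clusters:
            ref_seq = units[c.reference].seq
            best_name, best_id = None, -1.0
            for name, seq in references.items():
                ident = max(global_identity(ref_seq, seq, backend=backend),
                            global_identity(ref_seq, revcomp(seq), backend=backend))
                if ident > best_id:
                    best_name, best_id = name, ident
            c.label = best_name if best_id >= threshold else "unlabeled"
        return clustering
    ranked = sorted(clusters, key=lambda c: (-c.size, c.cluster_id))
    ranked[0].label = "M1"
    if len(ranked) > 1:
        ranked[1].label = "M2"
    for c in ranked[2:]:
        for big, like in ((ranked[0], "M1-like"),
                          (ranked[1], "M2-like") if len(ranked) > 1 else (None, None)):
            if big is None:
                continue
            ident = global_identity(units[c.reference].seq,
                                    units[big.reference].seq, backend="edlib")
            if ident >= threshold:
                c.label = like
                break
        else:
            c.label = "unlabeled"
    return clustering


# ---------------------------------------------------------------------------
# region grammar


@dataclass
class GrammarString:
    region_ref: str
    tokens: list[str]          # over {M1, M2, other}
    spacers: list[int]         # gaps between consecutive M1 copies (end to start)
    pattern: str
    well_formed: bool
    violations: list[str] = field(default_factory=list)


def _compress_pattern(tokens: list[str]) -> str:
    if not tokens:
        return "()"
    # canonical (M1-M2){n}-M1 form when applicable
    n = (len(tokens) - 1) // 2
    if (len(tokens) % 2 == 1 and n >= 1
            and all(t == "M1" for t in tokens[::2])
            and all(t == "M2" for t in tokens[1::2])):
        return f"(M1-M2){{{n}}}-M1"
    if len(tokens) == 1:
        return f"({tokens[0]})"
    return "-".join(tokens)


def validate_grammar(region_units: list[RepeatUnit], labels: list[str],
                     spacer: int = 140, spacer_tol: int = 60) -> GrammarString:
    """Check a region's ordered, labeled units against the repeat grammar.

    Rules: (1) M2 never occurs without at least one M1; (2) M1 may stand
    alone; (3) consecutive M1 copies are separated by about ``spacer``
    nt (end-to-start, within ``spacer_tol``); (4) between any two M2
    copies there is an M1.
    """
    if len(region_units) != len(labels):
        raise ValueError("one label per unit required")
    if any(lab == "unlabeled" for lab in labels):
        raise ValueError("units must be labeled before grammar validation")
    order = np.argsort([u.start for u in region_units])
    units = [region_units[i] for i in order]
    toks = []
    for i in order:
        lab = labels[i]
        toks.append("M1" if lab in ("M1", "M1-like")
                    else "M2" if lab in ("M2", "M2-like") else "other")
    violations = []
    if "M2" in toks and "M1" not in toks:
        violations.append("M2 without M1")
    m1_idx = [i for i, t in enumerate(toks) if t == "M1"]
    spacers = []
    for a, b in zip(m1_idx[:-1], m1_idx[1:]):
        gap = units[b].start - units[a].end
        spacers.append(int(gap))
        if not (spacer - spacer_tol <= gap <= spacer + spacer_tol):
            violations.append(f"M1 spacing {gap} outside {spacer}+-{spacer_tol}")
    m2_idx = [i for i, t in enumerate(toks) if t == "M2"]
    for a, b in zip(m2_idx[:-1], m2_idx[1:]):
        if not any(a < i < b for i in m1_idx):
            violations.append("adjacent M2 copies without intervening M1")
    region_ref = units[0].region_ref if units else ""
    return GrammarString(region_ref=region_ref, tokens=toks, spacers=spacers,
                         pattern=_compress_pattern(toks),
                         well_formed=not violations, violations=violations)


# ---------------------------------------------------------------------------
# TSD / TIR


def detect_tsd(genome: CircularGenome, start: int, end: int,
               max_len: int = 6) -> str | None:
    """Longest exact duplication flanking both ends of [start, end).

    The flanks are read on the circular sequence, so elements at the
    linearization boundary are handled.  Returns None when even the
    single flanking base differs.
    """
    for l in range(max_len, 0, -1):
        left = genome.fetch(start - l, start)
        right = genome.fetch(end, end + l)
        if left == right and "N" not in left:
            return left
    return None


def detect_tir(seq: str, min_tir: int = 10, min_identity: float = 0.8
               ) -> tuple[int, int]:
    """Terminal-inverted-repeat length of a putative palindromic element.

    Scans prefix lengths and aligns each prefix against the reverse
    complement of the equally long suffix; among lengths whose identity
    reaches ``min_identity``, the one maximizing matches minus edits is
    reported (so the TIR is not over-extended into diverged flanks).
    Returns (0, len) when no TIR of at least ``min_tir`` nt is found or
    for low-complexity (near-homopolymer) sequences.
    """
    L = len(seq)
    if L < 10:
        raise ValueError("unit too short for TIR detection")
    base_fracs = [seq.count(b) / L for b in "ACGT"]
    if max(base_fracs) >= 0.9:  # low-complexity guard
        return 0, L
    best_l, best_score = 0, 0
    for l in range(min_tir, L // 2 + 1):
        pre = seq[:l]
        suf_rc = revcomp(seq[L - l:])
        res = edlib.align(pre, suf_rc, mode="NW", task="distance")
        dist = res["editDistance"]
        cols = l + dist  # upper bound on columns; exact enough for scoring
        ident = (l - dist) / l
        if ident < min_identity:
            continue
        score = (l - dist) - dist
        if score > best_score:
            best_l, best_score = l, score
    if best_l == 0:
        return 0, L
    return best_l, L - 2 * best_l


# ---------------------------------------------------------------------------
# within- vs between-region identity


@dataclass
class IdentityComparison:
    within: np.ndarray
    between: np.ndarray
    statistic: float
    p_value: float


def identity_within_between(units: list[RepeatUnit], regions: list[str],
                            identity: np.ndarray | None = None,
                            subsample: bool = True, seed: int = 0,
                            backend: str = "auto") -> IdentityComparison:
    """Compare pairwise identities of repeats from the same vs different regions.

    All same-region pairs are used; different-region pairs are randomly
    subsampled to the same count (so both distributions carry equal
    weight), and a two-sided Wilcoxon rank-sum test is applied.
    """
    if len(units) != len(regions):
        raise ValueError("one region label per unit required")
    from collections import Counter
    usable = [r for r, c in Counter(regions).items() if c >= 2]
    if len(usable) < 2:
        raise ValueError("need at least 2 regions with at least 2 units each")
    if identity is None:
        identity = identity_matrix([u.seq for u in units], backend=backend)
    n = len(units)
    iu, ju = np.triu_indices(n, k=1)
    same = np.array([regions[i] == regions[j] for i, j in zip(iu, ju)])
    vals = identity[iu, ju]
    within = vals[same]
    between = vals[~same]
    if subsample and len(between) > len(within):
        rng = np.random.default_rng(seed)
        between = rng.choice(between, size=len(within), replace=False)
    stat, p = ranksums(within, between)
    return IdentityComparison(within=within, between=between,
                              statistic=float(stat), p_value=float(p))
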