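"""Pan/core-genome rarefaction, Heaps'-law openness, duplication
fractions, sliding-window core-gene density, RSCU and AAI.

The orthology input is a genome x HOG (hierarchical orthologous group)
gene-count matrix; presence means count >= 1.  Rarefaction adds genomes
iteratively over orderings of the genome set: at each step the core is
the set of HOGs present in every genome so far, the pan those present in
at least one, and "new" those absent from all previous genomes.  A
pan-genome is called open when the fitted Heaps'-law decay exponent
alpha of the new-HOG curve is below 1 and closed otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Data.CodonTable import standard_dna_table


@dataclass
class PanCoreCurve:
    """Mean/spread of core, pan and new-HOG counts per added genome."""

    n: np.ndarray
    core_mean: np.ndarray
    pan_mean: np.ndarray
    new_mean: np.ndarray
    core_sd: np.ndarray
    pan_sd: np.ndarray
    new_sd: np.ndarray
    n_orderings: int
    normalized: bool = False
    raw: dict[str, np.ndarray] | None = None  # per-ordering curves, if kept

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n, "core_mean": self.core_mean, "pan_mean": self.pan_mean,
                "new_mean": self.new_mean, "core_sd": self.core_sd,
                "pan_sd": self.pan_sd, "new_sd": self.new_sd,
            }
        )


def _orderings(n_genomes: int, max_combinations: int, seed: int) -> np.ndarray:
    """All genome orderings, or a seeded uniform sample when factorial
    explodes past the cap."""
    total = math.factorial(n_genomes)
    if total <= max_combinations:
        return np.array(list(itertools.permutations(range(n_genomes))))
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n_genomes) for _ in range(max_combinations)])


def _as_presence(matrix: pd.DataFrame) -> np.ndarray:
    m = np.asarray(matrix, dtype=int)
    if m.size == 0:
        raise ValueError("empty HOG matrix")
    return m >= 1


def pan_core_rarefaction(matrix: pd.DataFrame, max_combinations: int = 5000,
                         seed: int = 0, normalized: bool = False,
                         keep_orderings: bool = False) -> PanCoreCurve:
    """Iterative rarefaction of core/pan/new HOG counts over genome orderings.

    ``normalized`` rescales core and pan by their mean single-genome
    size so curves start at 1.0 (the convention used when comparing
    families of different genome sizes).
    """
    pres = _as_presence(matrix)
    G = pres.shape[0]
    if G < 2:
        raise ValueError("need at least 2 genomes")
    orders = _orderings(G, max_combinations, seed)
    R = len(orders)
    core = np.zeros((R, G))
    pan = np.zeros((R, G))
    new = np.zeros((R, G))
    for r, order in enumerate(orders):
        seen_any = np.zeros(pres.shape[1], dtype=bool)
        seen_all = np.ones(pres.shape[1], dtype=bool)
        for step, g in enumerate(order):
            row = pres[g]
            new[r, step] = np.count_nonzero(row & ~seen_any)
            seen_any |= row
            seen_all &= row
            core[r, step] = np.count_nonzero(seen_all)
            pan[r, step] = np.count_nonzero(seen_any)
    if normalized:
        base = pres.sum(axis=1).mean()
        core, pan = core / base, pan / base
    return PanCoreCurve(
        n=np.arange(1, G + 1),
        core_mean=core.mean(axis=0), pan_mean=pan.mean(axis=0),
        new_mean=new.mean(axis=0),
        core_sd=core.std(axis=0), pan_sd=pan.std(axis=0), new_sd=new.std(axis=0),
        n_orderings=R, normalized=normalized,
        raw={"core": core, "pan": pan, "new": new} if keep_orderings else None,
    )


@dataclass
class HeapsFit:
    """Heaps'-law fit E[new HOGs at genome n] = kappa * n**(-alpha)."""

    kappa: float
    alpha: float
    n_perm: int
    open: bool

    def __post_init__(self):
        self.open = bool(self.alpha < 1.0)


def fit_heaps(n: np.ndarray, new_mean: np.ndarray) -> tuple[float, float]:
    """Log-log least-squares fit of the decaying new-HOG curve.

    The first step (n=1, where "new" is the whole genome) is excluded;
    steps with zero mean new HOGs are dropped (log undefined).  Returns
    (kappa, alpha); alpha = +inf when fewer than 2 usable points remain.
    """
    n = np.asarray(n, dtype=float)
    y = np.asarray(new_mean, dtype=float)
    use = (n >= 2) & (y > 0)
    if use.sum() < 2:
        return float("nan"), float("inf")
    slope, intercept = np.polyfit(np.log(n[use]), np.log(y[use]), 1)
    return float(np.exp(intercept)), float(-slope)


def heaps_alpha(matrix: pd.DataFrame, n_perm: int = 1000, seed: int = 0) -> HeapsFit:
    """Estimate the Heaps'-law openness exponent of a HOG matrix.

    New-HOG counts are recorded over ``n_perm`` random genome orderings
    (``n_perm=0`` uses the matrix's given genome order once -- useful
    when the accession order is meaningful) and the permutation-averaged
    curve is fitted by log-log least squares.  Open pan-genome <=>
    alpha < 1.
    """
    pres = _as_presence(matrix)
    G = pres.shape[0]
    if G < 3:
        raise ValueError("need at least 3 genomes for a Heaps fit")
    rng = np.random.default_rng(seed)
    orders = ([np.arange(G)] if n_perm == 0
              else [rng.permutation(G) for _ in range(n_perm)])
    new = np.zeros((len(orders), G))
    for r, order in enumerate(orders):
        seen = np.zeros(pres.shape[1], dtype=bool)
        for step, g in enumerate(order):
            new[r, step] = np.count_nonzero(pres[g] & ~seen)
            seen |= pres[g]
    kappa, alpha = fit_heaps(np.arange(1, G + 1), new.mean(axis=0))
    return HeapsFit(kappa=kappa, alpha=alpha, n_perm=n_perm, open=alpha < 1.0)


def duplication_fraction(matrix: pd.DataFrame, genome: str,
                         mode: str = "excess") -> float:
    """Percentage of a genome's genes that arose from duplication.

    ``mode='excess'`` counts copies in excess of one per HOG
    (sum of max(count-1, 0) over HOGs, divided by total genes);
    ``mode='multi'`` counts every member of a multi-copy HOG instead.
    """
    if genome not in matrix.index:
        raise KeyError(f"genome {genome!r} not in matrix")
    counts = np.asarray(matrix.loc[genome], dtype=int)
    total = counts.sum()
    if total == 0:
        return 0.0
    if mode == "excess":
        dup = np.maximum(counts - 1, 0).sum()
    elif mode == "multi":
        dup = counts[counts >= 2].sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * dup / total


def core_density_window(values: np.ndarray, window: int = 21) -> np.ndarray:
    """Sliding-window mean over genes ordered on a circular genome.

    ``values`` is one number per gene in genomic order -- a 0/1 core
    flag (A-mode: core-gene density) or the gene's HOG copy number
    (B-mode: mean copy number).  The window is centered and wraps the
    origin; with fewer genes than the window it shrinks to the gene
    count (with a warning).
    """
    import warnings

    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("no genes")
    if n < window:
        warnings.warn(f"only {n} genes; shrinking window from {window} to {n}")
        window = n
    half = window // 2
    ext = np.r_[v[-half:], v, v[: window - half - 1]]
    cs = np.cumsum(np.r_[0.0, ext])
    return (cs[window:] - cs[:-window]) / window


# ---------------------------------------------------------------------------
# RSCU

_TABLE = standard_dna_table
# synonymous families, excluding stop codons and the single-codon
# families Trp (TGG) and Met (ATG) whose RSCU is identically 1
_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    _FAMILIES.setdefault(_aa, []).append(_codon)
RSCU_CODONS = sorted(
    c for aa, codons in _FAMILIES.items() if len(codons) > 1 for c in codons
)


def rscu(cds_seqs: list[str]) -> pd.Series:
    """Relative synonymous codon usage over a set of CDS sequences.

    All codons are pooled (whole-genome usage); RSCU of codon *c* coding
    amino acid *a* is count(c) * n_synonyms(a) / count(a).  Stop codons
    and the single-codon Trp/Met families are excluded (59 codons).
    Families whose amino acid never occurs yield NaN.
    """
    counts: dict[str, int] = {c: 0 for c in _TABLE.forward_table}
    for i, seq in enumerate(cds_seqs):
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS #{i} length {len(seq)} not a multiple of 3")
        for p in range(0, len(seq), 3):
            codon = seq[p : p + 3]
            if codon in counts:
                counts[codon] += 1
    out = {}
    for aa, codons in _FAMILIES.items():
        if len(codons) == 1:
            continue
        aa_total = sum(counts[c] for c in codons)
        for c in codons:
            out[c] = (counts[c] * len(codons) / aa_total) if aa_total else float("nan")
    return pd.Series(out).sort_index()


# ---------------------------------------------------------------------------
# AAI


@dataclass
class AAIResult:
    genome_a: str
    genome_b: str
    aai_pct: float
    n_pairs: int
    min_identity: float
    min_frac: float

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0 and not math.isnan(self.aai_pct)


def _protein_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(scoring="blastp")
    al.mode = "local"
    return al


def _best_hits(a: dict[str, str], b: dict[str, str], aligner,
               min_identity: float, min_frac: float) -> dict[str, tuple[str, float]]:
    """Best-scoring subject per query; value = (subject, identity %).
    Pairs failing the identity or aligned-fraction filter are dropped."""
    out: dict[str, tuple[str, float]] = {}
    for qid, qseq in a.items():
        best = None  # (score, sid, identity)
        for sid, sseq in b.items():
            aln = aligner.align(qseq, sseq)
            try:
                top = aln[0]
            except IndexError:  # no positive-scoring local alignment
                continue
            counts = top.counts()
            aligned_cols = top.length
            shorter = min(len(qseq), len(sseq))
            ident = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
            frac = aligned_cols / shorter if shorter else 0.0
            if ident < min_identity or frac < min_frac:
                continue
            if best is None or top.score > best[0]:
                best = (top.score, sid, ident)
        if best is not None:
            out[qid] = (best[1], best[2])
    return out


def aai(proteome_a: dict[str, str], proteome_b: dict[str, str],
        name_a: str = "a", name_b: str = "b",
        min_identity: float = 15.0, min_frac: float = 0.4) -> AAIResult:
    """Two-way average amino-acid identity between two proteomes.

    Reciprocal best hits by local protein alignment (BLOSUM62); pairs
    are kept when identity >= ``min_identity`` % and the alignment
    covers >= ``min_frac`` of the shorter protein.  The AAI is the mean
    identity over reciprocal pairs, averaged over both directions.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    aligner = _protein_aligner()
    ab = _best_hits(proteome_a, proteome_b, aligner, min_identity, min_frac)
    ba = _best_hits(proteome_b, proteome_a, aligner, min_identity, min_frac)
    idents = []
    for qid, (sid, ident_ab) in ab.items():
        back = ba.get(sid)
        if back is not None and back[0] == qid:
            idents.append((ident_ab + back[1]) / 2.0)
    if not idents:
        return AAIResult(name_a, name_b, float("nan"), 0, min_identity, min_frac)
    return AAIResult(name_a, name_b, float(np.mean(idents)), len(idents),
                     min_identity, min_frac)
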