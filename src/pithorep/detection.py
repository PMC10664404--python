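"""Repeat-rich region detection on circular genomes.

The pipeline mirrors classic self-dotplot repeat mapping:

(i)   the genome is aligned against itself (both strands) and hits are
      filtered at an E-value threshold;
(ii)  per-position alignment multiplicity is accumulated into a vector
      ``y`` -- a flattened dotplot;
(iii) ``y`` is smoothed by a circular sliding mean (window 500 nt) into
      ``ys`` and segments where ``ys`` exceeds a threshold
      tau = mean(ys) / sensitivity are reported as repeat-rich regions;
(iv)  within each region, individual repeat units are delimited at the
      local maxima of the smoothed absolute derivative of ``y``
      (smoothing window 20 nt, cutoff 10).

The internal aligner is a seed-and-extend word matcher (exact words,
ungapped X-drop extension, BLASTN-compatible E-values from the ungapped
Karlin-Altschul statistics for match +1 / mismatch -2).  Precomputed
hits in 12-column tabular format can be imported instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import CircularGenome, revcomp, seq_to_array

# Karlin-Altschul parameters for ungapped nucleotide alignment with
# reward +1 / penalty -2 (BLASTN defaults for these scores).
_KA_LAMBDA = 1.28
_KA_K = 0.46


@dataclass(frozen=True)
class AlignmentHit:
    """One local self-alignment hit, 0-based half-open, both intervals
    on the forward (linearized) coordinate system."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # "+" or "-"
    identity_pct: float
    evalue: float

    def __post_init__(self):
        if self.q_end <= self.q_start or self.s_end <= self.s_start:
            raise ValueError("empty hit interval")


@dataclass
class DetectionParams:
    """Tunable parameters of the detection pipeline.

    ``region_window`` is 500 nt for repeat mapping and 4000 nt when
    regions are defined for gene-level statistics.  ``sensitivity``
    divides the mean of the smoothed coverage to give the detection
    threshold tau (``tau_mode='divide'``); ``tau_mode='affine'``
    computes mean * sensitivity - 1 instead.
    """

    evalue_max: float = 1e-10
    region_window: int = 500
    derivative_window: int = 20
    derivative_cutoff: float = 10.0
    sensitivity: float = 2.5
    word_size: int = 11
    xdrop: int = 25
    tau_mode: str = "divide"
    min_region_length: int | None = None  # default region_window // 5
    max_word_occurrence: int = 10_000

    def __post_init__(self):
        for name in ("evalue_max", "region_window", "derivative_window",
                     "derivative_cutoff", "sensitivity", "word_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def effective_min_region_length(self) -> int:
        if self.min_region_length is not None:
            return self.min_region_length
        return self.region_window // 5


@dataclass
class CoverageProfile:
    """Per-position alignment multiplicity and its smoothed form."""

    genome_id: str
    y: np.ndarray        # integer multiplicity, length L
    ys: np.ndarray       # circular sliding mean of y
    window: int
    tau: float
    sensitivity: float


@dataclass
class RepeatRegion:
    genome_id: str
    start: int
    end: int
    mean_ys: float
    wrapped: bool = False  # piece of a run crossing the linearization origin

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatUnit:
    region_ref: str
    start: int
    end: int
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# step (i): self-alignment


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer integers at every start; -1 where the word spans N."""
    L = len(codes)
    n = L - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    km = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for t in range(k):
        c = codes[t : t + n]
        km = km * 4 + np.minimum(c, 3)
        bad |= c == 4
    km[bad] = -1
    return km


def _group_positions(km: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort k-mers; return (sorted values, argsort order, group boundaries)."""
    order = np.argsort(km, kind="stable")
    vals = km[order]
    bounds = np.flatnonzero(np.r_[True, vals[1:] != vals[:-1], True])
    return vals, order, bounds


def _self_pairs(km: np.ndarray, max_occ: int) -> tuple[np.ndarray, np.ndarray]:
    """All position pairs (i < j) sharing an exact word."""
    vals, order, bounds = _group_positions(km)
    out_i, out_j = [], []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        m = b1 - b0
        if m < 2 or vals[b0] < 0 or m > max_occ:
            continue
        pos = np.sort(order[b0:b1])
        ii, jj = np.triu_indices(m, k=1)
        out_i.append(pos[ii])
        out_j.append(pos[jj])
    if not out_i:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(out_i), np.concatenate(out_j)


def _cross_pairs(km_a: np.ndarray, km_b: np.ndarray, max_occ: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """All position pairs (i in a, j in b) sharing an exact word."""
    vals_a, order_a, bounds_a = _group_positions(km_a)
    vals_b, order_b, bounds_b = _group_positions(km_b)
    starts_a = bounds_a[:-1]
    uniq_a = vals_a[starts_a]
    out_i, out_j = [], []
    gb = 0
    n_groups_b = len(bounds_b) - 1
    for g, va in enumerate(uniq_a):
        if va < 0:
            continue
        # advance pointer in b's sorted unique values
        while gb < n_groups_b and vals_b[bounds_b[gb]] < va:
            gb += 1
        if gb >= n_groups_b or vals_b[bounds_b[gb]] != va:
            continue
        a0, a1 = bounds_a[g], bounds_a[g + 1]
        b0, b1 = bounds_b[gb], bounds_b[gb + 1]
        ma, mb = a1 - a0, b1 - b0
        if ma * mb > max_occ * max_occ:
            continue
        pa = order_a[a0:a1]
        pb = order_b[b0:b1]
        out_i.append(np.repeat(pa, mb))
        out_j.append(np.tile(pb, ma))
    if not out_i:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(out_i), np.concatenate(out_j)


def _dedup_segments(i: np.ndarray, j: np.ndarray, k: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse seed pairs to one representative per (diagonal, block run).

    Seeds from the same pair of repeat copies share a diagonal; blocks of
    128 nt on a diagonal are merged into segments [i_min, i_max + k).
    """
    if len(i) == 0:
        return (np.empty(0, dtype=np.int64),) * 3
    d = j - i
    block = i >> 7
    key = d * (1 << 40) + block
    order = np.lexsort((i, key))
    i, j, d, key, block = i[order], j[order], d[order], key[order], block[order]
    # new segment when diagonal changes or block jumps by > 1
    new = np.r_[True, (d[1:] != d[:-1]) | (block[1:] - block[:-1] > 1)]
    seg_id = np.cumsum(new) - 1
    n_seg = seg_id[-1] + 1
    seg_i0 = np.full(n_seg, np.iinfo(np.int64).max)
    seg_i1 = np.zeros(n_seg, dtype=np.int64)
    np.minimum.at(seg_i0, seg_id, i)
    np.maximum.at(seg_i1, seg_id, i)
    seg_d = d[new]
    return seg_i0, seg_i1 + k, seg_d


def _xdrop_extend(a: np.ndarray, b: np.ndarray, q0: np.ndarray, q1: np.ndarray,
                  d: np.ndarray, xdrop: int) -> tuple[np.ndarray, np.ndarray]:
    """Ungapped X-drop extension of segments (query a, subject b = a[i+d])."""
    la, lb = len(a), len(b)

    def _one_side(start: np.ndarray, step: int) -> np.ndarray:
        pos = start.copy()
        best_pos = start - step  # exclusive frontier of accepted extension
        cur = np.zeros(len(start), dtype=np.int64)
        best = np.zeros(len(start), dtype=np.int64)
        active = np.arange(len(start))
        while len(active):
            p = pos[active]
            sp = p + d[active]
            inb = (p >= 0) & (p < la) & (sp >= 0) & (sp < lb)
            ok = np.zeros(len(active), dtype=bool)
            if inb.any():
                pa = p[inb]
                pb = sp[inb]
                ok[inb] = (a[pa] == b[pb]) & (a[pa] != 4)
            cur[active] += np.where(ok, 1, -2)
            cur[active[~inb]] = -(10 ** 9)
            improved = cur[active] > best[active]
            idx = active[improved]
            best[idx] = cur[idx]
            best_pos[idx] = pos[idx]
            pos[active] += step
            keep = (best[active] - cur[active] <= xdrop) & inb
            active = active[keep]
        return best_pos

    left = _one_side(q0 - 1, -1)   # leftmost accepted position (q0 if none)
    right = _one_side(q1, +1)      # rightmost accepted position (q1-1 if none)
    return left, right + 1         # new [start, end)


def _segment_matches(a: np.ndarray, b: np.ndarray, q0: np.ndarray, q1: np.ndarray,
                     d: np.ndarray, chunk: int = 50_000) -> np.ndarray:
    """Exact match counts over [q0, q1) vs the shifted subject, chunked."""
    n = len(q0)
    out = np.zeros(n, dtype=np.int64)
    for c0 in range(0, n, chunk):
        c1 = min(n, c0 + chunk)
        lens = (q1[c0:c1] - q0[c0:c1]).astype(np.int64)
        total = int(lens.sum())
        if total == 0:
            continue
        reps = np.repeat(np.arange(c1 - c0), lens)
        offs = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
        qi = q0[c0:c1][reps] + offs
        si = qi + d[c0:c1][reps]
        eq = (a[qi] == b[si]) & (a[qi] != 4)
        out[c0:c1] = np.bincount(reps, weights=eq, minlength=c1 - c0).astype(np.int64)
    return out


def _hits_from_segments(a, b, i0, i1, d, params, L, strand):
    q0, q1 = _xdrop_extend(a, b, i0, i1, d, params.xdrop)
    keep = q1 > q0
    q0, q1, d = q0[keep], q1[keep], d[keep]
    if len(q0) == 0:
        return []
    matches = _segment_matches(a, b, q0, q1, d)
    lens = q1 - q0
    score = matches - 2 * (lens - matches)
    bits = (_KA_LAMBDA * score - np.log(_KA_K)) / np.log(2.0)
    with np.errstate(over="ignore"):  # hopeless segments overflow to inf
        evalue = float(L) * float(L) * np.power(2.0, -bits)
    keep = evalue <= params.evalue_max
    q0, q1, d, lens = q0[keep], q1[keep], d[keep], lens[keep]
    matches, evalue = matches[keep], evalue[keep]
    if len(q0) == 0:
        return []
    if strand == "+":
        s0, s1 = q0 + d, q1 + d
    else:
        # subject coordinates live on the reverse-complemented sequence
        s0 = L - (q1 + d)
        s1 = L - (q0 + d)
    # canonical orientation: query interval leftmost
    swap = q0 > s0
    q0n = np.where(swap, s0, q0)
    q1n = np.where(swap, s1, q1)
    s0n = np.where(swap, q0, s0)
    s1n = np.where(swap, q1, s1)
    rows = np.stack([q0n, q1n, s0n, s1n], axis=1)
    rows, idx = np.unique(rows, axis=0, return_index=True)
    ident = 100.0 * matches[idx] / lens[idx]
    ev = evalue[idx]
    return [
        AlignmentHit(int(r[0]), int(r[1]), int(r[2]), int(r[3]), strand,
                     float(pi), float(e))
        for r, pi, e in zip(rows, ident, ev)
    ]


def self_align(
    genome: CircularGenome,
    params: DetectionParams | None = None,
    backend: str = "internal",
    tabular_path=None,
) -> list[AlignmentHit]:
    """Align a genome against itself and return filtered hits.

    ``backend='internal'`` runs the built-in seed-and-extend aligner on
    both strands; ``backend='tabular-import'`` loads precomputed hits
    from a 12-column tabular file (the trivial full-length self-hit is
    dropped, symmetric duplicates are canonicalized).
    """
    params = params or DetectionParams()
    L = len(genome)
    if L == 0:
        raise ValueError("empty genome")
    if backend == "tabular-import":
        if tabular_path is None:
            raise ValueError("tabular-import backend requires tabular_path")
        return _import_tabular(tabular_path, L, params)
    if backend != "internal":
        raise ValueError(f"unknown backend {backend!r}")

    a = seq_to_array(genome.seq)
    rc = seq_to_array(revcomp(genome.seq))
    k = params.word_size
    km_f = _kmer_codes(a, k)
    hits: list[AlignmentHit] = []

    # forward strand: pairs i < j (diagonal > 0; the trivial self-hit on
    # the main diagonal is thereby excluded)
    i, j = _self_pairs(km_f, params.max_word_occurrence)
    i0, i1, d = _dedup_segments(i, j, k)
    hits += _hits_from_segments(a, a, i0, i1, d, params, L, "+")

    # reverse strand: forward genome vs its reverse complement
    km_r = _kmer_codes(rc, k)
    i, j = _cross_pairs(km_f, km_r, params.max_word_occurrence)
    i0, i1, d = _dedup_segments(i, j, k)
    minus = _hits_from_segments(a, rc, i0, i1, d, params, L, "-")
    hits += minus
    return hits


def _import_tabular(path, L: int, params: DetectionParams) -> list[AlignmentHit]:
    from .io import read_tabular_alignments

    df = read_tabular_alignments(path)
    hits = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.evalue > params.evalue_max:
            continue
        if (row.q_start, row.q_end, row.s_start, row.s_end) == (0, L, 0, L):
            continue  # trivial full-length self-hit
        if row.strand == "+" and row.q_start == row.s_start and row.q_end == row.s_end:
            continue
        if max(row.q_end, row.s_end) > L or min(row.q_start, row.s_start) < 0:
            raise ValueError(f"hit interval outside genome of length {L}")
        q0, q1, s0, s1 = row.q_start, row.q_end, row.s_start, row.s_end
        if q0 > s0:
            q0, q1, s0, s1 = s0, s1, q0, q1
        key = (q0, q1, s0, s1, row.strand)
        if key in seen:
            continue
        seen.add(key)
        hits.append(AlignmentHit(q0, q1, s0, s1, row.strand,
                                 float(row.identity_pct), float(row.evalue)))
    return hits


# ---------------------------------------------------------------------------
# step (ii): flattened dotplot


def coverage_vector(hits: list[AlignmentHit], L: int) -> np.ndarray:
    """Per-position count of how many hit intervals cover each position.

    Every hit contributes +1 over its query interval and +1 over its
    subject interval.
    """
    delta = np.zeros(L + 1, dtype=np.int64)
    for h in hits:
        for lo, hi in ((h.q_start, h.q_end), (h.s_start, h.s_end)):
            if lo < 0 or hi > L:
                raise IndexError(f"hit interval [{lo}, {hi}) outside genome length {L}")
            delta[lo] += 1
            delta[hi] -= 1
    return np.cumsum(delta[:-1])


# ---------------------------------------------------------------------------
# step (iii): smoothing and thresholding


def circular_sliding_mean(y: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean with circular wrap-around."""
    L = len(y)
    if window > L:
        raise ValueError(f"window {window} exceeds vector length {L}")
    half = window // 2
    ext = np.r_[y[-half:], y, y[: window - half - 1]]
    cs = np.cumsum(np.r_[0.0, ext])
    return (cs[window:] - cs[:-window]) / window


def smooth_threshold(y: np.ndarray, params: DetectionParams | None = None,
                     genome_id: str = "") -> CoverageProfile:
    """Smooth the coverage vector and derive the detection threshold tau."""
    params = params or DetectionParams()
    if len(y) <= params.region_window:
        raise ValueError("coverage vector not longer than the smoothing window")
    ys = circular_sliding_mean(np.asarray(y, dtype=float), params.region_window)
    mean_ys = float(ys.mean())
    if params.tau_mode == "divide":
        tau = mean_ys / params.sensitivity
    elif params.tau_mode == "affine":
        tau = mean_ys * params.sensitivity - 1.0
    else:
        raise ValueError(f"unknown tau_mode {params.tau_mode!r}")
    return CoverageProfile(genome_id=genome_id, y=np.asarray(y), ys=ys,
                           window=params.region_window, tau=tau,
                           sensitivity=params.sensitivity)


def detect_regions(profile: CoverageProfile,
                   params: DetectionParams | None = None) -> list[RepeatRegion]:
    """Maximal runs where ys > tau, as half-open intervals.

    Runs crossing the linearization origin are split at position 0 and
    both pieces are flagged ``wrapped``.  Runs shorter than the minimum
    region length (window/5 by default) are suppressed.
    """
    params = params or DetectionParams(region_window=profile.window,
                                       sensitivity=profile.sensitivity)
    ys, tau = profile.ys, profile.tau
    L = len(ys)
    mask = ys > tau
    if not mask.any():
        return []
    min_len = params.effective_min_region_length
    if mask.all():
        return [RepeatRegion(profile.genome_id, 0, L, float(ys.mean()))]
    # rotate so the vector starts inside a gap, then extract linear runs
    z = int(np.flatnonzero(~mask)[0])
    rolled = np.roll(mask, -z)
    change = np.flatnonzero(np.diff(rolled.astype(np.int8)))
    run_starts = change[rolled[change + 1]] + 1
    run_ends = change[~rolled[change + 1]] + 1
    if rolled[-1]:  # final run closes circularly at the rotation point
        run_ends = np.r_[run_ends, L]
    regions: list[RepeatRegion] = []
    for s, e in zip(run_starts, run_ends):
        if e - s < min_len:
            continue
        gs, ge = (int(s) + z) % L, (int(e) + z - 1) % L + 1
        vals = np.r_[ys[gs:], ys[:ge]] if gs >= ge else ys[gs:ge]
        mean_val = float(vals.mean())
        if gs < ge:
            regions.append(RepeatRegion(profile.genome_id, gs, ge, mean_val))
        else:  # run crosses the linearization origin: split and flag
            regions.append(RepeatRegion(profile.genome_id, gs, L, mean_val, wrapped=True))
            regions.append(RepeatRegion(profile.genome_id, 0, ge, mean_val, wrapped=True))
    regions.sort(key=lambda r: r.start)
    return regions


# ---------------------------------------------------------------------------
# step (iv): individual repeat retrieval


def _local_maxima(v: np.ndarray, cutoff: float) -> np.ndarray:
    """Strict 3-point local maxima above cutoff; plateaus -> leftmost."""
    # compress equal runs
    change = np.r_[True, v[1:] != v[:-1]]
    run_starts = np.flatnonzero(change)
    run_vals = v[run_starts]
    n = len(run_vals)
    if n == 0:
        return np.empty(0, dtype=int)
    left = np.r_[-np.inf, run_vals[:-1]]
    right = np.r_[run_vals[1:], -np.inf]
    is_max = (run_vals > left) & (run_vals > right) & (run_vals > cutoff)
    return run_starts[is_max]


def derivative_profile(y: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Smoothed absolute first derivative of the coverage vector.

    Sliding-mean smoothing (window ``derivative_window``) is applied to
    ``y`` before differencing and to the absolute derivative after.
    """
    w = params.derivative_window
    s1 = circular_sliding_mean(np.asarray(y, dtype=float), w)
    d = np.roll(s1, -1) - s1  # circular first difference
    return circular_sliding_mean(np.abs(d), w)


def split_units(profile: CoverageProfile, region: RepeatRegion,
                genome: CircularGenome | None = None,
                params: DetectionParams | None = None,
                filter_background: bool = True) -> list[RepeatUnit]:
    """Delimit individual repeat units within a detected region.

    Boundaries are local maxima of the smoothed |derivative| of ``y``
    exceeding the cutoff; maxima closer than the derivative window are
    merged to the strongest (delimiting steps of a single junction).
    When ``filter_background`` is set, flanking units whose mean raw
    coverage stays below tau (threshold-crossing overhang, not repeat
    sequence) are dropped; a region with no internal boundary yields a
    single unit spanning the region.
    """
    params = params or DetectionParams(region_window=profile.window,
                                       sensitivity=profile.sensitivity)
    sd = derivative_profile(profile.y, params)
    maxima = _local_maxima(sd, params.derivative_cutoff)
    inside = maxima[(maxima > region.start) & (maxima < region.end)]
    # merge boundary clusters closer than the derivative window
    boundaries: list[int] = []
    if len(inside):
        cluster = [int(inside[0])]
        for m in inside[1:]:
            if m - cluster[-1] <= params.derivative_window:
                cluster.append(int(m))
            else:
                boundaries.append(int(cluster[int(np.argmax(sd[cluster]))]))
                cluster = [int(m)]
        boundaries.append(int(cluster[int(np.argmax(sd[cluster]))]))
    edges = [region.start] + boundaries + [region.end]
    region_name = f"{profile.genome_id}:{region.start}-{region.end}"
    units = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        units.append(RepeatUnit(
            region_ref=region_name, start=lo, end=hi,
            seq=genome.fetch(lo, hi) if genome is not None else "",
        ))
    if filter_background and len(units) > 1:
        units = [u for u in units
                 if float(profile.y[u.start:u.end].mean()) >= profile.tau]
    return units


# ---------------------------------------------------------------------------
# convenience pipeline


@dataclass
class DetectionResult:
    hits: list[AlignmentHit]
    profile: CoverageProfile
    regions: list[RepeatRegion]          # raw threshold crossings
    units: list[RepeatUnit]
    refined_regions: list[RepeatRegion]  # trimmed to the span of retained units


def detect_repeats(genome: CircularGenome,
                   params: DetectionParams | None = None,
                   hits: list[AlignmentHit] | None = None) -> DetectionResult:
    """Run steps (i)-(iv) and refine region bounds to their unit spans.

    The threshold-crossing regions of step (iii) overshoot the true
    repeat span by up to half the smoothing window on each side; the
    refined regions are clipped to the first/last unit retained by the
    coverage filter of :func:`split_units`.
    """
    params = params or DetectionParams()
    if hits is None:
        hits = self_align(genome, params)
    y = coverage_vector(hits, len(genome))
    profile = smooth_threshold(y, params, genome_id=genome.id)
    regions = detect_regions(profile, params)
    units: list[RepeatUnit] = []
    refined: list[RepeatRegion] = []
    for reg in regions:
        reg_units = split_units(profile, reg, genome=genome, params=params)
        if not reg_units:
            continue
        lo = reg_units[0].start
        hi = reg_units[-1].end
        new_ref = f"{genome.id}:{lo}-{hi}"
        reg_units = [replace(u, region_ref=new_ref) for u in reg_units]
        units.extend(reg_units)
        refined.append(RepeatRegion(genome.id, lo, hi,
                                    float(profile.ys[lo:hi].mean()),
                                    wrapped=reg.wrapped))
    return DetectionResult(hits=hits, profile=profile, regions=regions,
                           units=units, refined_regions=refined)
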