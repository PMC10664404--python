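"""Synthetic genomes, orthology matrices and auxiliary tracks.

The generator emulates the observables of a repeat-invaded giant-virus
genome: a circular AT-rich sequence (~600 kb) carrying 100-300
repeat-rich regions, each an array of two palindromic element families
("M1": 54 nt terminal inverted repeats around a 37 nt internal sequence;
"M2": 47 nt TIRs around 37 nt) arranged as (M1-M2){n}-M1.  Consecutive
M1 copies are separated by ~140 nt of sequence that carries the M2
element, and every region is flanked by a short target-site duplication
(default "TA").  Planted truth (region and unit coordinates, family
labels) is emitted alongside the sequence so detection and clustering
can be scored against it.

Also provided: orthologous-group (HOG) count matrices with tunable
core/accessory/novel/duplication structure, per-position IPD-ratio
tracks, and codon-level sequence-pair evolution under a fixed dN/dS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CircularGenome, revcomp

BASES = np.array(list("ACGT"))


@dataclass
class FamilySpec:
    """One palindromic element family: TIR + internal sequence.

    ``divergence_rate`` is the per-site substitution probability applied
    independently to every planted copy relative to its (region)
    consensus.
    """

    label: str
    tir_length: int
    internal_length: int
    divergence_rate: float = 0.02

    @property
    def length(self) -> int:
        return 2 * self.tir_length + self.internal_length


def default_family_specs(divergence_rate: float = 0.02) -> list[FamilySpec]:
    """M1 (54/37/54 nt) and M2 (47/37/47 nt) palindromic families."""
    return [
        FamilySpec("M1", 54, 37, divergence_rate),
        FamilySpec("M2", 47, 37, divergence_rate),
    ]


@dataclass
class SimConfig:
    """Parameters of the planted-repeat genome generator.

    ``spacer_length`` is the median length of the sequence separating
    the end of one M1 copy from the start of the next within a region
    (the M2 element and its flanking TSDs sit inside this spacer);
    individual spacers jitter uniformly by up to ``spacer_jitter`` nt,
    mirroring the variable inter-element spacing of real repeat arrays,
    and each planted copy is truncated by up to ``end_jitter`` nt at
    either terminus, as real mobile-element copies typically are.
    ``region_drift`` mutates a per-region copy of each family consensus
    before the per-copy divergence is applied, giving repeats from the
    same region higher mutual identity than repeats from different
    regions.
    """

    genome_length: int = 600_000
    gc_fraction: float = 0.36
    repeat_gc_fraction: float = 0.24  # repeat arrays are markedly AT-richer
    n_regions: int = 100
    units_per_region_range: tuple[int, int] = (1, 8)
    family_specs: list[FamilySpec] = field(default_factory=default_family_specs)
    spacer_length: int = 140
    spacer_jitter: int = 4
    end_jitter: int = 4
    tsd: str = "TA"
    orf_density: float = 0.6
    region_drift: float = 0.0
    min_intergap: int = 800
    seed: int = 0


@dataclass
class SimResult:
    genome: CircularGenome
    regions: pd.DataFrame  # chrom, start, end, name, n_units
    units: pd.DataFrame    # chrom, start, end, name (family), score (copy idx), region
    genes: pd.DataFrame    # genome, gene_id, start, end, strand, in_repeat


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        # substitute to a uniformly chosen *different* base
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _family_consensus(rng: np.random.Generator, spec: FamilySpec, gc: float) -> str:
    tir = _random_dna(rng, spec.tir_length, gc)
    internal = _random_dna(rng, spec.internal_length, gc)
    return tir + internal + revcomp(tir)


class PlacementError(RuntimeError):
    """Regions cannot be placed without overlap at the requested density."""


def simulate_genome(cfg: SimConfig) -> SimResult:
    """Generate a circular genome with planted repeat-rich regions.

    Each region follows the grammar (M1-M2){n}-M1 with ``n`` drawn
    uniformly from ``units_per_region_range``; the region is flanked by
    the TSD on both sides and consecutive M1 copies are separated by
    ``spacer_length`` nt in the median.  Identical seeds give identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_regions > 0 and not cfg.family_specs:
        raise ValueError("family_specs must be nonempty when planting regions")
    lo, hi = cfg.units_per_region_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid units_per_region_range {cfg.units_per_region_range}")

    consensi = {
        s.label: _family_consensus(rng, s, cfg.repeat_gc_fraction)
        for s in cfg.family_specs
    }
    fam1 = cfg.family_specs[0] if cfg.family_specs else None
    fam2 = cfg.family_specs[1] if len(cfg.family_specs) > 1 else None
    tsd = cfg.tsd

    # Build region sequences and relative unit coordinates first.
    region_seqs: list[str] = []
    region_units: list[list[tuple[int, int, str, int]]] = []  # rel start, rel end, family, copy
    for r in range(cfg.n_regions):
        n = int(rng.integers(lo, hi + 1))
        ref = {
            lab: _mutate(rng, cons, cfg.region_drift) for lab, cons in consensi.items()
        }
        parts: list[str] = []
        units: list[tuple[int, int, str, int]] = []
        pos = 0
        copy_idx = {lab: 0 for lab in consensi}

        def emit(spec: FamilySpec) -> None:
            nonlocal pos
            copy = _mutate(rng, ref[spec.label], spec.divergence_rate)
            if cfg.end_jitter:
                t5 = int(rng.integers(0, cfg.end_jitter + 1))
                t3 = int(rng.integers(0, cfg.end_jitter + 1))
                copy = copy[t5 : len(copy) - t3]
            units.append((pos, pos + len(copy), spec.label, copy_idx[spec.label]))
            copy_idx[spec.label] += 1
            parts.append(copy)
            pos += len(copy)

        emit(fam1)
        for _ in range(n):
            # spacer between consecutive M1 copies, carrying M2 + TSDs;
            # uniform jitter (median-preserving) emulates the variable
            # inter-element spacing of real arrays
            jitter = (int(rng.integers(-cfg.spacer_jitter, cfg.spacer_jitter + 1))
                      if cfg.spacer_jitter else 0)
            if fam2 is not None:
                base_pad = cfg.spacer_length - fam2.length - 2 * len(tsd)
                if base_pad < 0:
                    raise ValueError(
                        f"spacer_length {cfg.spacer_length} too short for "
                        f"{fam2.label} ({fam2.length} nt) plus TSDs"
                    )
                # jitter widens but never squeezes the inner padding below
                # a few nt on each side of the inner element
                pad = max(base_pad + abs(jitter), 4)
                left = pad // 2
                right = pad - left
                parts.append(_random_dna(rng, left, cfg.repeat_gc_fraction) + tsd)
                pos += left + len(tsd)
                emit(fam2)
                parts.append(tsd + _random_dna(rng, right, cfg.repeat_gc_fraction))
                pos += len(tsd) + right
            else:
                parts.append(_random_dna(rng, max(cfg.spacer_length + jitter, 1),
                                         cfg.repeat_gc_fraction))
                pos += max(cfg.spacer_length + jitter, 1)
            emit(fam1)
        region_seqs.append("".join(parts))
        region_units.append(units)

    # Distribute regions around the circle with background in between
    # (one gap before each region plus one closing gap after the last,
    # so no region abuts the linearization origin).
    lengths = [len(s) for s in region_seqs]
    occupied = sum(lengths) + cfg.n_regions * 2 * len(tsd)
    n_gaps = cfg.n_regions + 1 if cfg.n_regions > 0 else 1
    free = cfg.genome_length - occupied - n_gaps * cfg.min_intergap
    if free < 0:
        raise PlacementError(
            f"{cfg.n_regions} regions ({occupied} nt + gaps) exceed genome length "
            f"{cfg.genome_length}"
        )
    extra = rng.multinomial(free, np.full(n_gaps, 1.0 / n_gaps))
    gap_lengths = cfg.min_intergap + extra

    chrom = f"sim_{cfg.seed}"
    pieces: list[str] = []
    pos = 0
    region_rows = []
    unit_rows = []
    for r in range(cfg.n_regions):
        bg = _random_dna(rng, int(gap_lengths[r]), cfg.gc_fraction)
        pieces.append(bg + tsd)
        pos += len(bg) + len(tsd)
        start = pos
        pieces.append(region_seqs[r])
        for rel_s, rel_e, fam, copy in region_units[r]:
            unit_rows.append(
                {
                    "chrom": chrom, "start": start + rel_s, "end": start + rel_e,
                    "name": fam, "score": copy, "strand": "+", "region": f"region_{r:04d}",
                }
            )
        pos += lengths[r]
        region_rows.append(
            {
                "chrom": chrom, "start": start, "end": pos,
                "name": f"region_{r:04d}", "n_units": len(region_units[r]),
            }
        )
        pieces.append(tsd)
        pos += len(tsd)
    if cfg.n_regions == 0:
        pieces.append(_random_dna(rng, cfg.genome_length, cfg.gc_fraction))
        pos = cfg.genome_length
    else:
        pieces.append(_random_dna(rng, int(gap_lengths[-1]), cfg.gc_fraction))
        pos += int(gap_lengths[-1])
    seq = "".join(pieces)
    assert len(seq) == cfg.genome_length, (len(seq), cfg.genome_length)

    genome = CircularGenome(id=chrom, seq=seq, circular=True)
    regions = pd.DataFrame(
        region_rows, columns=["chrom", "start", "end", "name", "n_units"]
    )
    units = pd.DataFrame(
        unit_rows, columns=["chrom", "start", "end", "name", "score", "strand", "region"]
    )
    genes = _annotate_orfs(rng, chrom, cfg.genome_length, cfg.orf_density, regions)
    return SimResult(genome=genome, regions=regions, units=units, genes=genes)


def _annotate_orfs(
    rng: np.random.Generator, chrom: str, L: int, density: float, regions: pd.DataFrame
) -> pd.DataFrame:
    """Tile gene annotations along the genome at the requested density.

    Genes are coordinate annotations (interval + strand); they may fall
    inside planted repeat regions, in which case ``in_repeat`` is set by
    the midpoint rule against the truth regions.
    """
    rows = []
    pos = 0
    i = 0
    if density <= 0:
        return pd.DataFrame(
            columns=["genome", "gene_id", "start", "end", "strand", "in_repeat"]
        )
    starts = regions["start"].to_numpy() if len(regions) else np.empty(0)
    ends = regions["end"].to_numpy() if len(regions) else np.empty(0)
    while pos < L:
        glen = int(rng.integers(300, 1501))
        gap = int(glen * (1 - density) / max(density, 1e-9))
        start = pos + max(1, int(rng.integers(0, max(gap, 1) + 1)))
        end = start + glen
        if end >= L:
            break
        mid = (start + end) // 2
        in_rep = bool(np.any((starts <= mid) & (mid < ends)))
        rows.append(
            {
                "genome": chrom, "gene_id": f"{chrom}_g{i:05d}",
                "start": start, "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "in_repeat": in_rep,
            }
        )
        i += 1
        pos = end + max(1, gap // 2)
    return pd.DataFrame(rows, columns=["genome", "gene_id", "start", "end", "strand", "in_repeat"])


# ---------------------------------------------------------------------------
# HOG matrices


def simulate_hog_matrix(
    n_genomes: int,
    core_size: int,
    accessory_pool: int = 0,
    new_per_genome: int = 0,
    dup_rate: float = 0.0,
    seed: int = 0,
    accessory_presence: float = 0.5,
    new_decay: float = 0.0,
) -> pd.DataFrame:
    """Genome x HOG gene-count matrix with planted pan-genome structure.

    * every genome carries all ``core_size`` core HOGs;
    * each of ``accessory_pool`` HOGs is present in each genome
      independently with probability ``accessory_presence`` (a finite,
      quickly shared-out pool -> closed pan-genome);
    * genome *g* (1-based, in generation order) additionally receives
      ``round(new_per_genome * g**-new_decay)`` never-seen-before HOGs
      (constant influx -> open pan-genome);
    * a ``dup_rate`` fraction of all gene slots are extra copies added
      to HOGs already present in the genome.
    """
    if min(n_genomes, core_size, accessory_pool, new_per_genome) < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    genomes = [f"g{i:02d}" for i in range(n_genomes)]
    blocks = []
    names = []
    if core_size:
        blocks.append(np.ones((n_genomes, core_size), dtype=int))
        names += [f"core_{j:04d}" for j in range(core_size)]
    if accessory_pool:
        acc = (rng.random((n_genomes, accessory_pool)) < accessory_presence).astype(int)
        keep = acc.sum(axis=0) > 0
        blocks.append(acc[:, keep])
        names += [f"acc_{j:04d}" for j in np.flatnonzero(keep)]
    new_counts = [
        int(round(new_per_genome * (g + 1) ** (-new_decay))) if new_per_genome else 0
        for g in range(n_genomes)
    ]
    for g, k in enumerate(new_counts):
        if k:
            col = np.zeros((n_genomes, k), dtype=int)
            col[g, :] = 1
            blocks.append(col)
            names += [f"new_{genomes[g]}_{j:04d}" for j in range(k)]
    if not blocks:
        return pd.DataFrame(np.zeros((n_genomes, 0), dtype=int), index=genomes)
    counts = np.concatenate(blocks, axis=1)
    # extra copies: fraction dup_rate of final gene slots are duplicates
    if dup_rate > 0:
        for g in range(n_genomes):
            base = counts[g].sum()
            extra = int(round(base * dup_rate / (1.0 - dup_rate)))
            present = np.flatnonzero(counts[g] > 0)
            if extra and len(present):
                add = rng.multinomial(extra, np.full(len(present), 1.0 / len(present)))
                counts[g, present] += add
    return pd.DataFrame(counts, index=genomes, columns=names)


# ---------------------------------------------------------------------------
# IPD-ratio tracks


def simulate_ipd_track(
    genome_id: str,
    length: int,
    modified_per_kb: float,
    seed: int = 0,
    start: int = 0,
    baseline: float = 1.0,
    modified_ratio: float = 6.0,
) -> pd.DataFrame:
    """Per-position IPD-ratio track with Poisson-planted modified bases.

    Positions are modified (IPD ratio ``modified_ratio`` > 4.5)
    independently with probability ``modified_per_kb / 1000``; all other
    positions sit at ``baseline``.
    """
    rng = np.random.default_rng(seed)
    ratios = np.full(length, baseline)
    hit = rng.random(length) < modified_per_kb / 1000.0
    ratios[hit] = modified_ratio
    return pd.DataFrame(
        {
            "genome_id": genome_id,
            "position": np.arange(start, start + length),
            "ipd_ratio": ratios,
        }
    )


# ---------------------------------------------------------------------------
# Codon-pair evolution under a fixed dN/dS


def simulate_cds_pair(
    n_codons: int, omega: float, n_events: int, seed: int = 0
) -> tuple[str, str]:
    """Evolve two CDS copies from a common ancestor under selection.

    Substitution events are proposed uniformly along each branch; a
    proposal is accepted if synonymous, with probability ``omega`` if
    nonsynonymous, and rejected if it creates a stop codon.  The
    realized dN/dS of the pair therefore approximates ``omega``.
    """
    from .stats import CODON_AA  # local import avoids a cycle at module load

    rng = np.random.default_rng(seed)
    codons = [c for c, aa in CODON_AA.items() if aa != "*"]
    anc = [codons[i] for i in rng.integers(len(codons), size=n_codons)]

    def evolve(seq: list[str]) -> list[str]:
        seq = list(seq)
        for _ in range(n_events):
            i = int(rng.integers(n_codons))
            j = int(rng.integers(3))
            old = seq[i]
            base = "ACGT"[int(rng.integers(4))]
            if base == old[j]:
                continue
            new = old[:j] + base + old[j + 1:]
            if CODON_AA[new] == "*":
                continue
            if CODON_AA[new] == CODON_AA[old] or rng.random() < omega:
                seq[i] = new
        return seq

    a = evolve(anc)
    b = evolve(anc)
    return "".join(a), "".join(b)
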