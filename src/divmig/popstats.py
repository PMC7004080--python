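"""Sequence- and SNP-level population-genetic statistics.

Covers the marker-level toolbox used around the demographic inference:
Kimura two-parameter distances, haplotype diversity with Nei's sampling
variance, Hudson's F_ST from pairwise differences, Benjamini-Yekutieli
multiple-testing correction, four-gamete recombination filtering of
phased haplotype alignments, and genotype PCA.

Distances use pairwise deletion of gap/N columns (the common default in
alignment-based distance software).  The F_ST estimator is Hudson's
1 - Hw/Hb; the haplotype-diversity variance is Nei (1987).  Both stand in
for the unstated internals of the desktop programs typically used for
Sanger data, and are validated against brute-force oracles in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HaplotypeAlignment",
    "k2p_distance",
    "haplotype_diversity",
    "hudson_fst",
    "by_adjust",
    "four_gamete_blocks",
    "FourGameteResult",
    "pca_genotypes",
    "read_fasta_alignment",
    "write_fasta_alignment",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = frozenset("ACGT")


class StatError(ValueError):
    """Raised for undefined statistics or invalid inputs."""


class SaturationError(StatError):
    """K2P distance undefined: observed divergence beyond model saturation."""


@dataclass
class HaplotypeAlignment:
    """Equal-length haplotype sequences with individual/population metadata.

    ``copy_index`` distinguishes the two phased alleles of a diploid
    individual at nuclear loci (0/1); mitochondrial loci carry a single
    copy (index 0).
    """

    sequences: list[str]
    individuals: list[str]
    populations: list[str]
    locus: str = "locus"
    copy_index: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise StatError("alignment is empty")
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise StatError("sequences must have equal aligned length")
        n = len(self.sequences)
        if len(self.individuals) != n or len(self.populations) != n:
            raise StatError("metadata must match number of sequences")
        if not self.copy_index:
            self.copy_index = [0] * n

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def subset(self, rows: Sequence[int]) -> "HaplotypeAlignment":
        return HaplotypeAlignment(
            [self.sequences[r] for r in rows],
            [self.individuals[r] for r in rows],
            [self.populations[r] for r in rows],
            self.locus,
            [self.copy_index[r] for r in rows],
        )

    def by_population(self, pop: str) -> "HaplotypeAlignment":
        rows = [k for k, p in enumerate(self.populations) if p == pop]
        if not rows:
            raise StatError(f"no sequences labelled {pop!r}")
        return self.subset(rows)

    def columns(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    d = -0.5*ln(1 - 2P - Q) - 0.25*ln(1 - 2Q) with P and Q the transition
    and transversion proportions over columns where both sequences carry
    an unambiguous base (pairwise deletion of gaps and N).
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise StatError("sequences must have equal length")
    kept = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in _BASES or y not in _BASES:
            continue
        kept += 1
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if kept == 0:
        raise StatError("no comparable sites after pairwise deletion")
    p = transitions / kept
    q = transversions / kept
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined at P={p:.3f}, Q={q:.3f}: divergence saturated"
        )
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def haplotype_diversity(labels: Iterable) -> tuple[float, float]:
    """Haplotype diversity H with Nei's (1987) sampling standard deviation.

    H = n/(n-1) * (1 - sum p_i^2); the variance follows Nei's formula
    V(H) = 2/(n(n-1)) * {2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2}.
    """
    labels = list(labels)
    n = len(labels)
    if n < 2:
        raise StatError("haplotype diversity needs >= 2 sequences")
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    p = counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return h, float(np.sqrt(max(var, 0.0)))


def _site_frequencies(seqs: Sequence[str], col: int) -> dict[str, float] | None:
    counts: dict[str, int] = {}
    for s in seqs:
        base = s[col]
        if base in _BASES:
            counts[base] = counts.get(base, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return None
    return {b: c / total for b, c in counts.items()}


def hudson_fst(pop1: Sequence[str], pop2: Sequence[str]) -> float:
    """Hudson's F_ST = 1 - Hw/Hb from mean pairwise differences.

    Diversities are computed from per-site allele frequencies (mean
    pairwise difference with replacement: Hw_d = 1 - sum p_a^2 per site,
    Hb = 1 - sum p1_a*p2_a), so two populations of identical composition
    give exactly 0.  Hw averages the two populations with equal weight;
    sites lacking an unambiguous base in either population are dropped
    (pairwise deletion).  Result clamped to [-1, 1]; Hb = 0 raises.
    """
    if len(pop1) < 2 or len(pop2) < 2:
        raise StatError("each population needs >= 2 sequences")
    length = len(pop1[0])
    if any(len(s) != length for s in (*pop1, *pop2)):
        raise StatError("sequences must have equal aligned length")
    hw1 = hw2 = hb = 0.0
    used = 0
    for col in range(length):
        f1 = _site_frequencies(pop1, col)
        f2 = _site_frequencies(pop2, col)
        if f1 is None or f2 is None:
            continue
        used += 1
        hw1 += 1.0 - sum(p * p for p in f1.values())
        hw2 += 1.0 - sum(p * p for p in f2.values())
        hb += 1.0 - sum(f1.get(b, 0.0) * f2.get(b, 0.0) for b in _BASES)
    if used == 0:
        raise StatError("no comparable sites after pairwise deletion")
    if hb == 0:
        raise StatError("between-population diversity is zero: F_ST undefined")
    return float(np.clip(1.0 - 0.5 * (hw1 + hw2) / hb, -1.0, 1.0))


def by_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Yekutieli step-up adjusted p-values (dependence-robust FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise StatError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_by")[1])


@dataclass
class FourGameteResult:
    """Longest four-gamete-compatible interval of an alignment.

    ``start``/``end`` are 0-based half-open column coordinates in the
    input alignment; ``alignment`` is the corresponding sub-alignment.
    """

    start: int
    end: int
    alignment: HaplotypeAlignment
    segregating_sites: list[int]
    note: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def _biallelic_columns(aln: HaplotypeAlignment) -> list[tuple[int, np.ndarray]]:
    cols = aln.columns()
    out = []
    for c in range(cols.shape[1]):
        col = cols[:, c]
        valid = np.isin(col, list(_BASES))
        alleles = sorted(set(col[valid]))
        if len(alleles) == 2:
            coded = np.full(col.shape, -1)
            coded[col == alleles[0]] = 0
            coded[col == alleles[1]] = 1
            out.append((c, coded))
    return out


def _incompatible(a: np.ndarray, b: np.ndarray) -> bool:
    both = (a >= 0) & (b >= 0)
    combos = set(zip(a[both].tolist(), b[both].tolist()))
    return len(combos) == 4


def four_gamete_blocks(alignment: HaplotypeAlignment) -> FourGameteResult:
    """Longest contiguous run of columns with no internal four-gamete pair.

    Two biallelic columns are incompatible when all four haplotypic
    combinations occur (evidence of recombination between them under
    infinite sites).  The leftmost longest compatible interval is
    returned, in alignment coordinates; with no segregating sites the
    whole locus is returned with an explanatory note.
    """
    sites = _biallelic_columns(alignment)
    length = alignment.length
    if not sites:
        return FourGameteResult(
            0, length, alignment, [],
            note="no biallelic segregating sites: whole locus retained",
        )
    positions = [c for c, _ in sites]
    coded = [v for _, v in sites]
    s = len(sites)
    # incompatibility lookup over segregating-site indices
    incompat = np.zeros((s, s), dtype=bool)
    for a in range(s):
        for b in range(a + 1, s):
            if _incompatible(coded[a], coded[b]):
                incompat[a, b] = incompat[b, a] = True
    # sliding window over segregating sites: widest compatible [lo, hi]
    best_lo, best_hi = 0, 0  # segregating-site index range, inclusive
    best_span = -1
    lo = 0
    for hi in range(s):
        while any(incompat[hi, x] for x in range(lo, hi)):
            lo += 1
        # alignment-coordinate span of a window: it may extend to the
        # column before the nearest incompatible site on either side
        left_bound = positions[lo - 1] + 1 if lo > 0 else 0
        right_bound = positions[hi + 1] if hi + 1 < s else length
        span = right_bound - left_bound
        if span > best_span or (span == best_span and left_bound < best_lo):
            best_span = span
            best_lo, best_hi = left_bound, right_bound
    sub = HaplotypeAlignment(
        [seq[best_lo:best_hi] for seq in alignment.sequences],
        alignment.individuals,
        alignment.populations,
        alignment.locus,
        alignment.copy_index,
    )
    seg_in_block = [p - best_lo for p in positions if best_lo <= p < best_hi]
    return FourGameteResult(best_lo, best_hi, sub, seg_in_block)


def pca_genotypes(
    genotypes: np.ndarray, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a diploid genotype matrix (individuals x sites, codes 0/1/2).

    Each site is centred by twice its allele frequency and scaled by the
    binomial standard deviation sqrt(2*p*(1-p)); monomorphic sites are
    dropped.  Returns per-individual coordinates and the fraction of
    variance per component.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise StatError("need a 2-D matrix with >= 2 individuals")
    if np.any((g < 0) | (g > 2)):
        raise StatError("genotype codes must be 0/1/2 with no missing data")
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise StatError("all sites are monomorphic: PCA undefined")
    g = g[:, poly]
    p = p[poly]
    x = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    lam = s**2
    if lam.sum() == 0:
        raise StatError("zero total variance: PCA undefined")
    varfrac = lam / lam.sum()
    coords = u * s
    if n_components is not None:
        coords = coords[:, :n_components]
        varfrac = varfrac[:n_components]
    return coords, varfrac


# ---------------------------------------------------------------------------
# FASTA I/O — headers encode "individual|population|copy"
# ---------------------------------------------------------------------------

def write_fasta_alignment(aln: HaplotypeAlignment, path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(seq), id=f"{ind}|{pop}|{copy}", description=""
        )
        for seq, ind, pop, copy in zip(
            aln.sequences, aln.individuals, aln.populations, aln.copy_index
        )
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta_alignment(path: str | Path, locus: str | None = None) -> HaplotypeAlignment:
    from Bio.SeqIO import parse as seqio_parse

    seqs, inds, pops, copies = [], [], [], []
    for rec in seqio_parse(str(path), "fasta"):
        parts = rec.id.split("|")
        seqs.append(str(rec.seq))
        inds.append(parts[0])
        pops.append(parts[1] if len(parts) > 1 else "pop1")
        copies.append(int(parts[2]) if len(parts) > 2 else 0)
    return HaplotypeAlignment(
        seqs, inds, pops, locus or Path(path).stem, copies
    )
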