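"""Joint allele-frequency spectra: construction, folding, masking, serialization.

The central observable of the pipeline is the joint AFS between two
populations: an (2*n1+1) x (2*n2+1) matrix (diploid samples, haploid axis
units) whose entry (i, j) counts segregating sites at which the alternate
allele was seen on i of the population-1 haplotypes and j of the
population-2 haplotypes.  Without an outgroup the ancestral state is
unknown and the spectrum is folded onto minor-allele counts.

File serialization follows the dadi text dialect: a header line with the
two axis dimensions and the fold state, a line of flattened row-major
values, and a line of flattened mask indicators (1 = masked).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "JointSFS",
    "afs_from_genotypes",
    "fold_spectrum",
    "read_sfs",
    "write_sfs",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
]

MISSING = -1


class SpectrumError(ValueError):
    """Raised for malformed spectra or spectrum files."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype codes (0/1/2, -1 = missing) with population labels.

    ``genotypes`` is an (n_individuals, n_sites) integer array; each
    individual carries a population label, restricted here to two
    populations (``pop1``/``pop2`` by convention, but any two labels work).
    """

    genotypes: np.ndarray
    individuals: list[str]
    populations: list[str]
    sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise SpectrumError("genotypes must be a 2-D individuals x sites array")
        n_ind, n_sites = self.genotypes.shape
        if len(self.individuals) != n_ind or len(self.populations) != n_ind:
            raise SpectrumError("individual ids / population labels must match rows")
        if not self.sites:
            self.sites = [f"site{k}" for k in range(n_sites)]
        if len(self.sites) != n_sites:
            raise SpectrumError("site ids must match columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise SpectrumError("genotype codes must be 0, 1, 2 or -1 (missing)")
        for pop in set(self.populations):
            if self.populations.count(pop) < 1:  # pragma: no cover - tautology
                raise SpectrumError(f"population {pop} has no individuals")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def pop_rows(self, pop: str) -> np.ndarray:
        rows = np.array([k for k, p in enumerate(self.populations) if p == pop])
        if rows.size == 0:
            raise SpectrumError(f"no individuals labelled {pop!r}")
        return rows

    def pop_labels(self) -> list[str]:
        """Distinct population labels in sorted order (stable under any
        reordering of individuals)."""
        return sorted(set(self.populations))


@dataclass
class JointSFS:
    """Joint AFS with mask and fold state.

    ``data[i, j]`` holds site counts (or expected counts); ``mask`` marks
    entries that carry no information — the absorbing corners (0, 0) and
    (n1, n2) always, plus everything beyond half the total sample after
    folding.
    """

    data: np.ndarray
    folded: bool = False
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SpectrumError("spectrum must be a 2-D matrix")
        if self.mask is None:
            self.mask = self.default_mask(self.data.shape, self.folded)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise SpectrumError("mask shape must match data shape")
        # masked entries carry no mass
        self.data = np.where(self.mask, 0.0, self.data)

    @staticmethod
    def default_mask(shape: tuple[int, int], folded: bool) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[0, 0] = True
        mask[-1, -1] = True
        if folded:
            n1, n2 = shape[0] - 1, shape[1] - 1
            i, j = np.indices(shape)
            mask |= (i + j) > (n1 + n2) / 2.0
        return mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def sample_sizes(self) -> tuple[int, int]:
        """Haploid sample sizes (n1, n2)."""
        return self.shape[0] - 1, self.shape[1] - 1

    def total(self) -> float:
        """Total unmasked mass (number of segregating sites tallied)."""
        return float(self.data[~self.mask].sum())

    def fold(self) -> "JointSFS":
        return fold_spectrum(self)

    def copy(self) -> "JointSFS":
        return JointSFS(self.data.copy(), folded=self.folded, mask=self.mask.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JointSFS):
            return NotImplemented
        return (
            self.folded == other.folded
            and self.shape == other.shape
            and np.array_equal(self.mask, other.mask)
            and np.allclose(self.data, other.data)
        )


def afs_from_genotypes(g: GenotypeMatrix, pops: Sequence[str] | None = None) -> JointSFS:
    """Tally the unfolded joint AFS from diploid genotypes.

    Each diploid contributes two haplotypes; entry (i, j) counts sites with
    i alternate alleles among population-1 haplotypes and j among
    population-2 haplotypes.  Missing data must have been filtered by the
    caller — allele counts, not frequencies, are tallied.
    """
    if (g.genotypes == MISSING).any():
        raise SpectrumError(
            "genotype matrix contains missing data; filter sites (or individuals) "
            "with missing calls before building the spectrum"
        )
    if pops is None:
        labels = g.pop_labels()
        if len(labels) != 2:
            raise SpectrumError(
                f"expected exactly two populations, found {labels}; pass pops=(p1, p2)"
            )
        pops = labels
    rows1, rows2 = g.pop_rows(pops[0]), g.pop_rows(pops[1])
    n1 = 2 * rows1.size
    n2 = 2 * rows2.size
    i_counts = g.genotypes[rows1].sum(axis=0)
    j_counts = g.genotypes[rows2].sum(axis=0)
    data = np.zeros((n1 + 1, n2 + 1))
    np.add.at(data, (i_counts, j_counts), 1.0)
    mono = float(data[0, 0] + data[n1, n2])
    sfs = JointSFS(data, folded=False)
    if sfs.total() == 0 and mono > 0:
        warnings.warn(
            "all sites are monomorphic: the spectrum mass sits entirely in the "
            "masked corners",
            stacklevel=2,
        )
    return sfs


def fold_spectrum(s: JointSFS) -> JointSFS:
    """Fold an unfolded joint spectrum onto minor-allele counts.

    With S = n1 + n2 total haploids, entry (i, j) with i+j < S/2 receives
    the mass of its complement (n1-i, n2-j); entries on the hinge
    i+j = S/2 are averaged with their complement; entries past the hinge
    are masked.  Total unmasked mass is conserved.
    """
    if s.folded:
        raise SpectrumError("spectrum is already folded")
    n1, n2 = s.sample_sizes
    total_hap = n1 + n2
    i, j = np.indices(s.shape)
    below = (i + j) < total_hap / 2.0
    hinge = (i + j) * 2 == total_hap
    comp = s.data[::-1, ::-1]  # value at (n1-i, n2-j)
    data = np.zeros_like(s.data)
    data[below] = s.data[below] + comp[below]
    data[hinge] = (s.data[hinge] + comp[hinge]) / 2.0
    mask = JointSFS.default_mask(s.shape, folded=True)
    # entries masked pre-fold stay masked only if their complement is also masked
    mask |= s.mask & s.mask[::-1, ::-1]
    return JointSFS(data, folded=True, mask=mask)


# ---------------------------------------------------------------------------
# serialization: dadi text dialect
# ---------------------------------------------------------------------------

def write_sfs(sfs: JointSFS, path: str | Path) -> None:
    """Write a spectrum in the dadi text dialect (dims, values, mask lines)."""
    d1, d2 = sfs.shape
    lines = [
        f"{d1} {d2} {'folded' if sfs.folded else 'unfolded'}",
        " ".join(repr(float(v)) for v in sfs.data.ravel()),
        " ".join("1" if m else "0" for m in sfs.mask.ravel()),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sfs(path: str | Path) -> JointSFS:
    """Read a spectrum written by :func:`write_sfs` (dadi text dialect)."""
    raw = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(raw) < 2:
        raise SpectrumError(f"{path}: expected header and value lines")
    header = raw[0].split()
    if len(header) < 2:
        raise SpectrumError(f"{path}: header must give two dimensions")
    try:
        d1, d2 = int(header[0]), int(header[1])
    except ValueError as exc:
        raise SpectrumError(f"{path}: non-integer dimensions in header") from exc
    folded = len(header) > 2 and header[2].lower() == "folded"
    values = np.array([float(v) for v in raw[1].split()])
    if values.size != d1 * d2:
        raise SpectrumError(
            f"{path}: header promises {d1}x{d2}={d1 * d2} values, found {values.size}"
        )
    mask = None
    if len(raw) > 2:
        mask_vals = np.array([int(v) for v in raw[2].split()])
        if mask_vals.size != d1 * d2:
            raise SpectrumError(f"{path}: mask length does not match dimensions")
        mask = mask_vals.reshape(d1, d2).astype(bool)
    return JointSFS(values.reshape(d1, d2), folded=folded, mask=mask)


# ---------------------------------------------------------------------------
# genotype matrix I/O
# ---------------------------------------------------------------------------

def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """TSV with one row per individual: id, population, then 0/1/2/NA codes."""
    df = pd.DataFrame(g.genotypes, index=g.individuals, columns=g.sites)
    df = df.astype(object).where(df != MISSING, "NA")
    df.insert(0, "population", g.populations)
    df.to_csv(path, sep="\t", index_label="individual")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual", dtype=str,
                     keep_default_na=False)
    if "population" not in df.columns:
        raise SpectrumError(f"{path}: missing 'population' column")
    pops = df.pop("population").tolist()
    geno = df.replace("NA", str(MISSING)).astype(np.int64).to_numpy()
    return GenotypeMatrix(geno, list(df.index), pops, list(df.columns))


def read_genotypes_vcf(
    path: str | Path, populations: dict[str, str]
) -> GenotypeMatrix:
    """Minimal VCF reader: biallelic sites, diploid GT fields only.

    ``populations`` maps sample id -> population label.  Any ploidy other
    than diploid raises; missing GT becomes the missing code.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        unknown = [s for s in samples if s not in populations]
        if unknown:
            raise SpectrumError(f"samples without population label: {unknown}")
        rows: list[list[int]] = [[] for _ in samples]
        site_ids: list[str] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise SpectrumError(
                    f"{path}: site {rec.chrom}:{rec.pos} is not biallelic"
                )
            site_ids.append(f"{rec.chrom}:{rec.pos}")
            for k, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or all(a is None for a in gt):
                    rows[k].append(MISSING)
                    continue
                if len(gt) != 2 or any(a is None for a in gt):
                    raise SpectrumError(
                        f"{path}: sample {sample} at {rec.chrom}:{rec.pos} is not "
                        "a called diploid genotype"
                    )
                rows[k].append(int(gt[0]) + int(gt[1]))
    geno = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(geno, samples, [populations[s] for s in samples], site_ids)
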