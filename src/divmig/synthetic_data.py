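"""Seeded structured-coalescent data generator with known ground truth.

Emulates the study system end to end: two diploid populations (default 9
vs 5 individuals, the empirical sample sizes) genotyped at a large panel
of unlinked biallelic SNPs; multi-locus Sanger-style haplotype alignments
with a deeply divergent mitochondrial locus (inheritance scalar 0.25, one
sequence per individual) and shallower nuclear loci (scalar 1.0, two
phased sequences per individual); and a maternally cotransmitted symbiont
label per individual, flipped to the other lineage with a small lateral
transfer probability to emulate host-symbiont discordance.

Every generator is reproducible bit-for-bit from (config, seed).  SNP
sites are drawn one independent genealogy per site under the divergence
scenario's time-inhomogeneous structured coalescent and conditioned on
segregation by placing a single mutation uniformly on the genealogy.
Sequence loci evolve by per-branch Poisson mutation with a Kimura
two-parameter rate matrix on a single genealogy per locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _coalescent
from .demography import (
    DemographicModelSpec,
    Epoch,
    ModelSpecError,
    backward_arrays,
    epoch_schedule,
)
from .popstats import HaplotypeAlignment
from .spectra import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_snp_genotypes",
    "simulate_locus_alignments",
    "simulate_host_symbiont_dataset",
]

_POP_LABELS = ("pop1", "pop2")
_BASE_ORDER = "ACGT"
# K2P partners: transition target, the two transversion targets
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth scenario plus sampling and mutation settings.

    Defaults mirror the study conditions: 9 vs 5 diploids, a SNP panel on
    the 349k-site scale with per-site theta matching the fitted ancestral
    mutation scaling (~0.035 = theta/L), three 518-bp sequence loci, a
    transition/transversion ratio of 2, and a ~15% symbiont
    lateral-transfer probability (15 discordant of 97 clams genotyped).
    """

    model_spec: DemographicModelSpec
    n1: int = 9
    n2: int = 5
    num_snp_sites: int = 349_288
    num_loci: int = 3
    locus_length: int = 518
    theta_site: float = 0.035
    ts_tv_ratio: float = 2.0
    inheritance_scalar: float = 1.0
    transfer_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 0:
            raise ModelSpecError("n1 >= 1 and n2 >= 0 required")
        if self.theta_site <= 0:
            raise ModelSpecError("theta_site must be > 0")
        if not 0.0 <= self.transfer_prob <= 1.0:
            raise ModelSpecError("transfer_prob must lie in [0, 1]")
        if not 0.0 < self.inheritance_scalar <= 1.0:
            raise ModelSpecError("inheritance_scalar must lie in (0, 1]")
        if self.num_snp_sites < 1:
            raise ModelSpecError("num_snp_sites must be >= 1")
        if self.locus_length < 1:
            raise ModelSpecError("locus_length must be >= 1")
        if self.ts_tv_ratio <= 0:
            raise ModelSpecError("ts_tv_ratio must be > 0 (may be inf)")

    def individual_ids(self) -> tuple[list[str], list[str]]:
        ids = [f"ag_{k + 1}" for k in range(self.n1)] + [
            f"ps_{k + 1}" for k in range(self.n2)
        ]
        pops = [_POP_LABELS[0]] * self.n1 + [_POP_LABELS[1]] * self.n2
        return ids, pops


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside simulated data.

    Regenerating with the same :class:`SimulationConfig` reproduces both
    data and truth bit-for-bit.
    """

    model_id: str
    parameters: dict
    seed: int
    snp_tmrca: np.ndarray | None = None
    snp_migration_class: np.ndarray | None = None
    locus_summaries: list[dict] = field(default_factory=list)
    symbiont_source: list[str] = field(default_factory=list)
    symbiont_flipped: list[bool] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_id": self.model_id,
            "parameters": self.parameters,
            "seed": self.seed,
            "snp_tmrca": None
            if self.snp_tmrca is None
            else [float(v) for v in self.snp_tmrca],
            "snp_migration_class": None
            if self.snp_migration_class is None
            else [int(v) for v in self.snp_migration_class],
            "locus_summaries": self.locus_summaries,
            "symbiont_source": self.symbiont_source,
            "symbiont_flipped": [bool(b) for b in self.symbiont_flipped],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _derive_seed(seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(seed), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % 2**31)


def _truth_params(spec: DemographicModelSpec) -> dict:
    return {k: float(v) for k, v in spec.free_values().items()} | {
        "theta": float(spec.theta)
    }


def _scaled_backward(epochs: tuple[Epoch, ...], scalar: float):
    """Backward arrays with all deme sizes (incl. ancestral) scaled."""
    dur, nu1, nu2, m12, m21 = backward_arrays(epochs)
    return dur, nu1 * scalar, nu2 * scalar, m12, m21


def _masks_to_haplotypes(mask: np.ndarray, n_hap: int) -> np.ndarray:
    """(n_sites,) int64 bitmask array -> (n_hap, n_sites) 0/1 matrix."""
    bits = (mask[None, :] >> np.arange(n_hap)[:, None]) & 1
    return bits.astype(np.int64)


def simulate_snp_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Unlinked biallelic SNP genotypes under the configured scenario.

    Each site is an independent structured-coalescent genealogy accepted
    by rejection sampling with probability proportional to its total
    branch length — the exact infinite-sites conditioning on observing a
    segregating site — after which a single mutation is placed uniformly
    on the branches.  For 2M models the rejection loop includes the
    migration-class draw (neutral rate with probability P), so accepted
    class fractions are length-weighted, consistent with the P-weighted
    expected-spectrum mixture used in fitting.  Returns 0/1/2 diploid
    genotype codes plus per-site TMRCA and class truth.
    """
    spec = config.model_spec
    n1h, n2h = 2 * config.n1, 2 * config.n2
    if n1h > 62 or n2h > 62:
        raise ModelSpecError("at most 31 diploids per population supported")
    components = epoch_schedule(spec)
    n_sites = config.num_snp_sites
    # component 0 is the neutral-rate class with weight P; single-class
    # models pass the same schedule twice with p = 1
    dur_a, nu1_a, nu2_a, m12_a, m21_a = backward_arrays(components[0][1])
    if len(components) == 1:
        p_class_a = 1.0
        dur_b, nu1_b, nu2_b, m12_b, m21_b = dur_a, nu1_a, nu2_a, m12_a, m21_a
    else:
        p_class_a = components[0][0]
        dur_b, nu1_b, nu2_b, m12_b, m21_b = backward_arrays(components[1][1])

    def l_bound(dur):
        # near-certain total-length bound: every lineage alive through all
        # finite epochs plus a >40-coalescent-unit ancestral allowance
        # (tail probability < 1e-17)
        return (n1h + n2h) * (float(dur[np.isfinite(dur)].sum()) + 45.0)

    mask1 = np.empty(n_sites, dtype=np.int64)
    mask2 = np.empty(n_sites, dtype=np.int64)
    tmrca = np.empty(n_sites, dtype=np.float64)
    site_class = np.empty(n_sites, dtype=np.int64)
    _coalescent.simulate_sites(
        n1h, n2h,
        dur_a, nu1_a, nu2_a, m12_a, m21_a,
        dur_b, nu1_b, nu2_b, m12_b, m21_b,
        p_class_a, l_bound(dur_a), l_bound(dur_b),
        n_sites, _derive_seed(config.seed, 2), mask1, mask2, tmrca, site_class,
    )
    hap1 = _masks_to_haplotypes(mask1, n1h)
    hap2 = _masks_to_haplotypes(mask2, n2h)
    haps = np.vstack([hap1, hap2])  # (n1h + n2h, n_sites)
    geno = haps[0::2, :] + haps[1::2, :]
    ids, pops = config.individual_ids()
    matrix = GenotypeMatrix(geno, ids, pops)
    truth = SimulationTruth(
        model_id=spec.model_id,
        parameters=_truth_params(spec),
        seed=config.seed,
        snp_tmrca=tmrca,
        snp_migration_class=site_class if len(components) > 1 else None,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# sequence loci
# ---------------------------------------------------------------------------

def _sample_genealogy(dur, nu1, nu2, m12, m21, tip_demes: list[int], rng):
    """Gillespie structured-coalescent tree; returns (parent, time) arrays.

    Nodes 0..n-1 are tips (time 0); internal nodes are appended in
    coalescence order; the last node is the MRCA.
    """
    n = len(tip_demes)
    parent = -np.ones(2 * n - 1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    deme = list(tip_demes)
    n_epochs = len(dur)
    e = 0
    t_epoch = 0.0
    t_global = 0.0
    next_node = n
    while len(active) > 1:
        k1 = deme.count(0)
        k2 = len(active) - k1
        c1 = 0.5 * k1 * (k1 - 1) / nu1[e]
        c2 = 0.5 * k2 * (k2 - 1) / nu2[e]
        mg = k1 * m12[e] + k2 * m21[e]
        rate = c1 + c2 + mg
        advance = rate <= 0
        dt = 0.0
        if not advance:
            dt = rng.exponential(1.0 / rate)
            if e < n_epochs - 1 and t_epoch + dt > dur[e]:
                advance = True
        if advance:
            t_global += dur[e] - t_epoch
            e += 1
            t_epoch = 0.0
            if e == n_epochs - 1:
                deme = [0] * len(active)
            continue
        t_epoch += dt
        t_global += dt
        u = rng.random() * rate
        if u < c1 + c2:
            d = 0 if u < c1 else 1
            members = [i for i, dd in enumerate(deme) if dd == d]
            a, b = rng.choice(len(members), size=2, replace=False)
            ia, ib = members[a], members[b]
            node = next_node
            next_node += 1
            node_time[node] = t_global
            parent[active[ia]] = node
            parent[active[ib]] = node
            keep_deme = deme[ia]
            for idx in sorted((ia, ib), reverse=True):
                active.pop(idx)
                deme.pop(idx)
            active.append(node)
            deme.append(keep_deme)
        else:
            v = u - c1 - c2
            if v < k1 * m12[e]:
                members = [i for i, dd in enumerate(deme) if dd == 0]
                deme[members[int(rng.integers(len(members)))]] = 1
            else:
                members = [i for i, dd in enumerate(deme) if dd == 1]
                deme[members[int(rng.integers(len(members)))]] = 0
    return parent, node_time


def _evolve_k2p(parent, node_time, n_tips, length, theta_site, ts_tv_ratio, rng):
    """Evolve sequences down the tree with per-branch Poisson K2P events."""
    n_nodes = parent.shape[0]
    root = n_nodes - 1
    if np.isinf(ts_tv_ratio):
        p_transition = 1.0
    else:
        p_transition = ts_tv_ratio / (ts_tv_ratio + 1.0)
    seqs: list[np.ndarray | None] = [None] * n_nodes
    seqs[root] = rng.integers(4, size=length)
    # children lists for top-down traversal
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for node in range(n_nodes - 1):
        children[parent[node]].append(node)
    base_idx = {b: i for i, b in enumerate(_BASE_ORDER)}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children[node]:
            seq = seqs[node].copy()
            blen = node_time[node] - node_time[child]
            n_mut = rng.poisson(length * 0.5 * theta_site * blen)
            for _ in range(n_mut):
                pos = int(rng.integers(length))
                base = _BASE_ORDER[seq[pos]]
                if rng.random() < p_transition:
                    seq[pos] = base_idx[_TRANSITION[base]]
                else:
                    seq[pos] = base_idx[_TRANSVERSIONS[base][int(rng.integers(2))]]
            seqs[child] = seq
            stack.append(child)
    return ["".join(_BASE_ORDER[b] for b in seqs[k]) for k in range(n_tips)]


def simulate_locus_alignments(
    config: SimulationConfig, mitochondrial: bool | None = None
) -> list[HaplotypeAlignment]:
    """Linked-sequence loci: one genealogy per locus, finite-sites K2P.

    Deme sizes within each locus are scaled by the inheritance scalar
    (0.25 reproduces the reduced effective size of the mitochondrial
    genome).  Mitochondrial loci sample one sequence per individual,
    nuclear loci two; by default a locus is treated as mitochondrial
    whenever the inheritance scalar is below 1.
    """
    if config.num_loci < 1:
        raise ModelSpecError("num_loci must be >= 1")
    if mitochondrial is None:
        mitochondrial = config.inheritance_scalar < 1.0
    spec = config.model_spec
    components = epoch_schedule(spec)
    copies = 1 if mitochondrial else 2
    ids, pops = config.individual_ids()
    tip_demes = [0] * (config.n1 * copies) + [1] * (config.n2 * copies)
    out: list[HaplotypeAlignment] = []
    for locus in range(config.num_loci):
        rng = np.random.default_rng(_derive_seed(config.seed, 3, locus))
        if len(components) == 1:
            epochs = components[0][1]
        else:
            epochs = components[0][1] if rng.random() < components[0][0] else components[1][1]
        dur, nu1, nu2, m12, m21 = _scaled_backward(epochs, config.inheritance_scalar)
        parent, node_time = _sample_genealogy(dur, nu1, nu2, m12, m21, tip_demes, rng)
        seqs = _evolve_k2p(
            parent, node_time, len(tip_demes), config.locus_length,
            config.theta_site, config.ts_tv_ratio, rng,
        )
        seq_ids = [ind for ind in ids for _ in range(copies)]
        seq_pops = [pop for pop in pops for _ in range(copies)]
        copy_idx = [c for _ in ids for c in range(copies)]
        out.append(
            HaplotypeAlignment(
                seqs, seq_ids, seq_pops,
                locus=f"mt{locus + 1}" if mitochondrial else f"nuc{locus + 1}",
                copy_index=copy_idx,
            )
        )
    return out


def locus_truth(config: SimulationConfig, alignments: list[HaplotypeAlignment]) -> SimulationTruth:
    """Truth sidecar for sequence loci (topology-level summaries)."""
    truth = SimulationTruth(
        model_id=config.model_spec.model_id,
        parameters=_truth_params(config.model_spec),
        seed=config.seed,
    )
    for aln in alignments:
        truth.locus_summaries.append(
            {"locus": aln.locus, "n_sequences": len(aln), "length": aln.length}
        )
    return truth


# ---------------------------------------------------------------------------
# host-symbiont dataset
# ---------------------------------------------------------------------------

def simulate_host_symbiont_dataset(
    config: SimulationConfig,
) -> tuple[HaplotypeAlignment, dict[str, str], SimulationTruth]:
    """Mitochondrial alignment plus per-individual symbiont labels.

    Each individual's symbiont label starts as its mitochondrial lineage's
    population of origin (the sampled population — maternal cotransmission)
    and is flipped to the other population's lineage label independently
    with probability ``transfer_prob``; flips are recorded in the truth.
    """
    mito_config = SimulationConfig(
        model_spec=config.model_spec,
        n1=config.n1,
        n2=config.n2,
        num_snp_sites=config.num_snp_sites,
        num_loci=1,
        locus_length=config.locus_length,
        theta_site=config.theta_site,
        ts_tv_ratio=config.ts_tv_ratio,
        inheritance_scalar=min(config.inheritance_scalar, 0.25),
        transfer_prob=config.transfer_prob,
        seed=config.seed,
    )
    aln = simulate_locus_alignments(mito_config, mitochondrial=True)[0]
    ids, pops = config.individual_ids()
    rng = np.random.default_rng(_derive_seed(config.seed, 4))
    flips = rng.random(len(ids)) < config.transfer_prob
    other = {_POP_LABELS[0]: _POP_LABELS[1], _POP_LABELS[1]: _POP_LABELS[0]}
    labels = {
        ind: (other[pop] if flip else pop)
        for ind, pop, flip in zip(ids, pops, flips)
    }
    truth = SimulationTruth(
        model_id=config.model_spec.model_id,
        parameters=_truth_params(config.model_spec),
        seed=config.seed,
        symbiont_source=list(pops),
        symbiont_flipped=[bool(f) for f in flips],
    )
    truth.locus_summaries.append(
        {"locus": aln.locus, "n_sequences": len(aln), "length": aln.length}
    )
    return aln, labels, truth
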