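"""Divergence scenarios and expected joint allele-frequency spectra.

Seven two-population divergence models are supported:

* ``SI``   strict isolation — split, then no gene flow for T_s;
* ``IM``   isolation-with-migration — continuous gene flow since the split;
* ``AM``   ancient migration — gene flow for T_am after the split, then
           isolation for T_s;
* ``SC``   secondary contact — isolation for T_s, then gene flow for T_sc;
* ``IM2M``/``AM2M``/``SC2M`` — the same histories with heterogeneous
  introgression: a fraction P of sites exchanges migrants at the neutral
  scaled rates (M12, M21) while the remainder (barrier loci) uses reduced
  effective rates (Me12, Me21).

Scalings follow the standard diffusion convention: sizes nu1, nu2 are
relative to the ancestral reference size N_ref (the ancestral population
has size 1), times are in units of 2*N_ref generations, migration
M = 2*N_ref*m with m the per-generation fraction of migrants, and
theta = 4*N_ref*mu*L sets the mutation scaling of the expected spectrum.

The expected spectrum entry (i, j) equals (theta/2)*E[L_ij], where L_ij is
the total branch length subtending exactly i of the population-1 and j of
the population-2 haplotypes.  E[L] is estimated by seeded Monte-Carlo over
independent structured-coalescent genealogies, so the spectrum (and hence
any likelihood built on it) is deterministic given the engine seed.
A discrete-generation Wright-Fisher simulator provides an independent
forward-time oracle for validating the coalescent-side scalings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import _coalescent
from .spectra import JointSFS

__all__ = [
    "DemographicModelSpec",
    "Epoch",
    "EngineConfig",
    "MODEL_IDS",
    "FREE_PARAMETERS",
    "epoch_schedule",
    "expected_afs",
    "wf_forward_oracle",
    "read_model_json",
    "write_model_json",
]


class ModelSpecError(ValueError):
    """Raised for invalid or inconsistent model parameterizations."""


MODEL_IDS = ("SI", "IM", "AM", "SC", "IM2M", "AM2M", "SC2M")

#: Free demographic parameters per model (theta is profiled, never counted).
FREE_PARAMETERS: dict[str, tuple[str, ...]] = {
    "SI": ("nu1", "nu2", "T_s"),
    "IM": ("nu1", "nu2", "M12", "M21", "T_s"),
    "AM": ("nu1", "nu2", "M12", "M21", "T_am", "T_s"),
    "SC": ("nu1", "nu2", "M12", "M21", "T_s", "T_sc"),
    "IM2M": ("nu1", "nu2", "M12", "M21", "Me12", "Me21", "T_s", "P"),
    "AM2M": ("nu1", "nu2", "M12", "M21", "Me12", "Me21", "T_am", "T_s", "P"),
    "SC2M": ("nu1", "nu2", "M12", "M21", "Me12", "Me21", "T_s", "T_sc", "P"),
}

_ALL_PARAMS = ("nu1", "nu2", "M12", "M21", "Me12", "Me21", "T_am", "T_sc", "T_s", "P")
_NONNEGATIVE = ("M12", "M21", "Me12", "Me21")
_POSITIVE = ("nu1", "nu2", "T_am", "T_sc", "T_s")


@dataclass(frozen=True)
class DemographicModelSpec:
    """One of the seven divergence scenarios with its scaled parameters.

    Parameters not applicable to ``model_id`` must be left ``None``.
    ``theta`` scales the expected spectrum and is not a free parameter of
    the divergence history (it is profiled analytically during fitting).
    """

    model_id: str
    nu1: float | None = None
    nu2: float | None = None
    M12: float | None = None
    M21: float | None = None
    Me12: float | None = None
    Me21: float | None = None
    T_am: float | None = None
    T_sc: float | None = None
    T_s: float | None = None
    P: float | None = None
    theta: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ModelSpecError(
                f"unknown model {self.model_id!r}; expected one of {MODEL_IDS}"
            )
        free = FREE_PARAMETERS[self.model_id]
        for name in _ALL_PARAMS:
            value = getattr(self, name)
            if name in free:
                if value is None:
                    raise ModelSpecError(f"{self.model_id}: parameter {name} required")
            elif value is not None:
                raise ModelSpecError(
                    f"{self.model_id}: parameter {name} is not applicable and must "
                    "be absent"
                )
        for name in _POSITIVE:
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ModelSpecError(f"{name} must be > 0, got {value}")
        for name in _NONNEGATIVE:
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ModelSpecError(f"{name} must be >= 0, got {value}")
        if self.P is not None and not 0.0 <= self.P <= 1.0:
            raise ModelSpecError(f"P must lie in [0, 1], got {self.P}")
        if self.theta <= 0:
            raise ModelSpecError(f"theta must be > 0, got {self.theta}")

    @property
    def k_free(self) -> int:
        """Number of free demographic parameters (theta excluded)."""
        return len(FREE_PARAMETERS[self.model_id])

    def free_values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FREE_PARAMETERS[self.model_id]}

    def with_theta(self, theta: float) -> "DemographicModelSpec":
        return replace(self, theta=theta)


class Epoch(NamedTuple):
    """A forward-time epoch: duration and constant sizes / migration.

    ``m12`` is the scaled rate 2*N_ref*m of migrants entering population 1
    from population 2 (and the backward rate at which a pop-1 lineage
    traces into pop 2); ``m21`` symmetrically.
    """

    duration: float
    nu1: float
    nu2: float
    m12: float
    m21: float


def epoch_schedule(
    spec: DemographicModelSpec,
) -> list[tuple[float, tuple[Epoch, ...]]]:
    """Forward-time epoch schedules with mixture weights.

    Returns ``[(weight, epochs), ...]`` where ``epochs`` runs forward in
    time from the split (the ancestral population, size 1, precedes the
    first epoch).  Plain models return a single component with weight 1;
    2M models return the neutral-rate component with weight P and the
    reduced-rate (barrier) component with weight 1 - P.
    """
    m = spec.model_id
    base = m.replace("2M", "")

    def sched(m12: float, m21: float) -> tuple[Epoch, ...]:
        if base == "SI":
            return (Epoch(spec.T_s, spec.nu1, spec.nu2, 0.0, 0.0),)
        if base == "IM":
            return (Epoch(spec.T_s, spec.nu1, spec.nu2, m12, m21),)
        if base == "AM":
            return (
                Epoch(spec.T_am, spec.nu1, spec.nu2, m12, m21),
                Epoch(spec.T_s, spec.nu1, spec.nu2, 0.0, 0.0),
            )
        if base == "SC":
            return (
                Epoch(spec.T_s, spec.nu1, spec.nu2, 0.0, 0.0),
                Epoch(spec.T_sc, spec.nu1, spec.nu2, m12, m21),
            )
        raise ModelSpecError(f"unhandled model {m!r}")  # pragma: no cover

    if base == "SI":
        return [(1.0, sched(0.0, 0.0))]
    if m.endswith("2M"):
        return [
            (spec.P, sched(spec.M12, spec.M21)),
            (1.0 - spec.P, sched(spec.Me12, spec.Me21)),
        ]
    return [(1.0, sched(spec.M12, spec.M21))]


def backward_arrays(
    epochs: tuple[Epoch, ...],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Backward-order epoch arrays for the coalescent kernels.

    Present-day epoch first; a terminal ancestral epoch (size 1, no
    migration, unbounded duration) is appended — entering it merges all
    lineages into the ancestral deme.
    """
    rev = list(epochs)[::-1]
    rev.append(Epoch(np.inf, 1.0, 1.0, 0.0, 0.0))
    dur = np.array([e.duration for e in rev])
    nu1 = np.array([e.nu1 for e in rev])
    nu2 = np.array([e.nu2 for e in rev])
    m12 = np.array([e.m12 for e in rev])
    m21 = np.array([e.m21 for e in rev])
    return dur, nu1, nu2, m12, m21


@dataclass(frozen=True)
class EngineConfig:
    """Monte-Carlo settings for the expected-spectrum engine.

    ``n_genealogies`` independent genealogies per mixture component;
    ``seed`` fixes the stream (common random numbers across likelihood
    evaluations make the fitted surface deterministic).
    """

    n_genealogies: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genealogies < 1:
            raise ModelSpecError("n_genealogies must be >= 1")


def _component_moments(
    epochs: tuple[Epoch, ...], n1_hap: int, n2_hap: int, cfg: EngineConfig
) -> tuple[np.ndarray, np.ndarray]:
    dur, nu1, nu2, m12, m21 = backward_arrays(epochs)
    l_sum = np.zeros((n1_hap + 1, n2_hap + 1))
    l_sq = np.zeros_like(l_sum)
    _coalescent.branch_length_moments(
        n1_hap, n2_hap, dur, nu1, nu2, m12, m21,
        cfg.n_genealogies, cfg.seed % 2**31, l_sum, l_sq,
    )
    k = cfg.n_genealogies
    mean = l_sum / k
    var = np.maximum(l_sq / k - mean**2, 0.0)
    se = np.sqrt(var / k)
    return mean, se


def expected_afs(
    spec: DemographicModelSpec,
    n1_hap: int,
    n2_hap: int,
    engine_config: EngineConfig | None = None,
    return_se: bool = False,
) -> JointSFS | tuple[JointSFS, np.ndarray]:
    """Expected unfolded joint AFS at the spec's theta.

    Entries scale linearly in theta; for 2M models the spectrum is the
    P-weighted mixture of the neutral- and reduced-rate components.
    Optionally also returns the per-entry Monte-Carlo standard error.
    """
    if n1_hap < 1 and n2_hap < 1:
        raise ModelSpecError("at least one haploid sample required")
    if n1_hap < 0 or n2_hap < 0:
        raise ModelSpecError("sample sizes must be non-negative")
    cfg = engine_config or EngineConfig()
    mean = np.zeros((n1_hap + 1, n2_hap + 1))
    sevar = np.zeros_like(mean)
    for weight, epochs in epoch_schedule(spec):
        if weight == 0.0:
            continue
        m, s = _component_moments(epochs, n1_hap, n2_hap, cfg)
        mean += weight * m
        sevar += (weight * s) ** 2
    data = 0.5 * spec.theta * mean
    se = 0.5 * spec.theta * np.sqrt(sevar)
    sfs = JointSFS(data, folded=False)
    if return_se:
        se[sfs.mask] = 0.0
        return sfs, se
    return sfs


# ---------------------------------------------------------------------------
# discrete Wright-Fisher forward oracle (used in validation only)
# ---------------------------------------------------------------------------

def wf_forward_oracle(
    spec: DemographicModelSpec,
    n1_hap: int,
    n2_hap: int,
    pop_size_units: int,
    reps: int,
    seed: int,
    return_se: bool = False,
) -> JointSFS | tuple[JointSFS, np.ndarray]:
    """Expected AFS from a discrete-generation two-deme Wright-Fisher model.

    Haploid demes of size 2*N_d individuals (N_d = N_ref*nu_d) evolve with
    per-generation migrant fractions m = M/(2*N_ref); genealogies of the
    sample are traced one generation at a time (parents drawn uniformly,
    simultaneous mergers allowed) through the epoch schedule mapped to
    generations, then through the ancestral deme.  Branch lengths are
    converted to coalescent units by 1/(2*N_ref).  Small sizes only: this
    is a validation oracle, not a production engine.
    """
    if pop_size_units > 200:
        raise ModelSpecError("pop_size_units > 200 refused: oracle is O(N*gens)")
    if n1_hap > 8 or n2_hap > 8:
        raise ModelSpecError("samples > 8 haplotypes/pop refused in the oracle")
    components = epoch_schedule(spec)
    rng = np.random.default_rng(seed)
    n1p, n2p = n1_hap + 1, n2_hap + 1
    l_sum = np.zeros((n1p, n2p))
    l_sq = np.zeros_like(l_sum)
    two_n = 2 * pop_size_units
    total_reps = 0
    for weight, epochs in components:
        comp_reps = int(round(weight * reps))
        if comp_reps == 0:
            continue
        total_reps += comp_reps
        # backward order: present epoch first, then ancestral
        back = list(epochs)[::-1]
        gens = [max(1, int(round(e.duration * two_n))) for e in back]
        sizes = [
            (max(2, int(round(two_n * e.nu1))), max(2, int(round(two_n * e.nu2))))
            for e in back
        ]
        migs = [(e.m12 / two_n, e.m21 / two_n) for e in back]
        for m12, m21 in migs:
            if m12 > 1 or m21 > 1:
                raise ModelSpecError("per-generation migrant fraction exceeds 1")
        for _ in range(comp_reps):
            l_loc = _wf_single_genealogy(
                n1_hap, n2_hap, gens, sizes, migs, two_n, rng
            )
            l_sum += l_loc
            l_sq += l_loc**2
    mean = l_sum / total_reps
    var = np.maximum(l_sq / total_reps - mean**2, 0.0)
    se = np.sqrt(var / total_reps)
    data = 0.5 * spec.theta * mean
    sfs = JointSFS(data, folded=False)
    if return_se:
        se_scaled = 0.5 * spec.theta * se
        se_scaled[sfs.mask] = 0.0
        return sfs, se_scaled
    return sfs


def _wf_single_genealogy(n1_hap, n2_hap, gens, sizes, migs, two_n, rng):
    n1p, n2p = n1_hap + 1, n2_hap + 1
    l_loc = np.zeros((n1p, n2p))
    # lineage: [deme, i-count, j-count]
    lineages = [[0, 1, 0] for _ in range(n1_hap)] + [[1, 0, 1] for _ in range(n2_hap)]
    inv_two_n = 1.0 / two_n

    def step(size1, size2, m12, m21):
        nonlocal lineages
        for lin in lineages:
            l_loc[lin[1], lin[2]] += inv_two_n
        parents: dict[tuple[int, int], list[int]] = {}
        for lin in lineages:
            d = lin[0]
            if d == 0:
                if m12 > 0 and rng.random() < m12:
                    d = 1
            else:
                if m21 > 0 and rng.random() < m21:
                    d = 0
            size = size1 if d == 0 else size2
            key = (d, int(rng.integers(size)))
            if key in parents:
                parents[key][1] += lin[1]
                parents[key][2] += lin[2]
            else:
                parents[key] = [d, lin[1], lin[2]]
        lineages = list(parents.values())

    for (size1, size2), (m12, m21), g in zip(sizes, migs, gens):
        for _ in range(g):
            if len(lineages) <= 1:
                break
            step(size1, size2, m12, m21)
    # ancestral phase: single deme of size two_n
    while len(lineages) > 1:
        for lin in lineages:
            lin[0] = 0
        step(two_n, two_n, 0.0, 0.0)
    return l_loc


# ---------------------------------------------------------------------------
# parameter-file I/O
# ---------------------------------------------------------------------------

def write_model_json(spec: DemographicModelSpec, path: str | Path) -> None:
    payload = {"model_id": spec.model_id, "theta": spec.theta}
    payload.update(spec.free_values())
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_model_json(path: str | Path) -> DemographicModelSpec:
    payload = json.loads(Path(path).read_text())
    if "model_id" not in payload:
        raise ModelSpecError(f"{path}: missing model_id")
    return DemographicModelSpec(**payload)
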