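"""Host-symbiont discordance: clade assignment and cross-tabulation.

Individuals are classified by their host mitochondrial haplotype
(mitotype) and their symbiont 16S sequence (ribotype) against labelled
reference alignments; the two assignments are cross-tabulated, with
off-diagonal cells flagging discordant individuals — the signal of
lateral symbiont transfer between maternally cotransmitted lineages.

Classification is nearest-clade by mean K2P distance: the reference
clades are deeply separated (~9% mitochondrial divergence between the
two host species), so distance-to-reference assignment is unambiguous in
practice; exact ties raise rather than assign silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .popstats import HaplotypeAlignment, k2p_distance

__all__ = [
    "AmbiguousAssignmentError",
    "DiscordanceTable",
    "assign_clade",
    "assign_alignment",
    "discordance_table",
]


class AssignmentError(ValueError):
    """Raised for invalid classification inputs."""


class AmbiguousAssignmentError(AssignmentError):
    """Query is (near-)equidistant between clades; no silent assignment."""


def assign_clade(
    query: str,
    references: HaplotypeAlignment,
    margin_threshold: float = 0.0,
) -> tuple[str, float]:
    """Assign a sequence to the reference clade of minimum mean K2P distance.

    ``references`` carries the clade label of each reference sequence in
    its population field.  Returns (label, margin) where the margin is the
    runner-up mean distance minus the winner's; a margin at or below
    ``margin_threshold`` raises :class:`AmbiguousAssignmentError`.
    """
    from .popstats import SaturationError

    clades = sorted(set(references.populations))
    if len(clades) < 2:
        raise AssignmentError("need references from at least two clades")
    means = {}
    for clade in clades:
        sub = references.by_population(clade)
        dists = []
        for ref in sub.sequences:
            try:
                dists.append(k2p_distance(query, ref))
            except SaturationError:
                # beyond K2P saturation: maximally distant from this clade
                dists.append(np.inf)
        means[clade] = float(np.mean(dists))
    ranked = sorted(means, key=lambda c: (means[c], c))
    winner, runner_up = ranked[0], ranked[1]
    if not np.isfinite(means[winner]):
        raise AmbiguousAssignmentError(
            "query is beyond K2P saturation from every reference clade"
        )
    margin = means[runner_up] - means[winner]
    if margin <= margin_threshold:
        raise AmbiguousAssignmentError(
            f"query equidistant between {winner} ({means[winner]:.5f}) and "
            f"{runner_up} ({means[runner_up]:.5f}); margin {margin:.2e}"
        )
    return winner, margin


def assign_alignment(
    queries: HaplotypeAlignment,
    references: HaplotypeAlignment,
    margin_threshold: float = 0.0,
) -> dict[str, str]:
    """Assign every individual in ``queries``; multi-sequence individuals
    (phased nuclear alleles) are assigned by consensus, ties raising."""
    per_individual: dict[str, list[str]] = {}
    for seq, ind in zip(queries.sequences, queries.individuals):
        label, _ = assign_clade(seq, references, margin_threshold)
        per_individual.setdefault(ind, []).append(label)
    out = {}
    for ind, labels in per_individual.items():
        values, counts = np.unique(labels, return_counts=True)
        top = counts.max()
        winners = [v for v, c in zip(values, counts) if c == top]
        if len(winners) > 1:
            raise AmbiguousAssignmentError(
                f"individual {ind}: allele assignments split {dict(zip(values, counts))}"
            )
        out[ind] = winners[0]
    return out


@dataclass
class DiscordanceTable:
    """Mitotype x ribotype contingency counts with per-individual calls."""

    counts: pd.DataFrame
    assignments: pd.DataFrame  # columns: individual, mitotype, ribotype, discordant

    @property
    def n_individuals(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_discordant(self) -> int:
        return int(self.assignments["discordant"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


def discordance_table(
    mito: dict[str, str], ribo: dict[str, str]
) -> DiscordanceTable:
    """Cross-tabulate host mitotype and symbiont ribotype assignments.

    Off-diagonal cells (mitotype clade != ribotype clade) are flagged
    discordant.  Both assignment sets must cover the same individuals.
    """
    missing_ribo = sorted(set(mito) - set(ribo))
    missing_mito = sorted(set(ribo) - set(mito))
    if missing_ribo or missing_mito:
        raise AssignmentError(
            f"unmatched individuals — no ribotype: {missing_ribo}; "
            f"no mitotype: {missing_mito}"
        )
    individuals = sorted(mito)
    rows = pd.DataFrame(
        {
            "individual": individuals,
            "mitotype": [mito[i] for i in individuals],
            "ribotype": [ribo[i] for i in individuals],
        }
    )
    rows["discordant"] = rows["mitotype"] != rows["ribotype"]
    labels = sorted(set(rows["mitotype"]) | set(rows["ribotype"]))
    counts = pd.crosstab(rows["mitotype"], rows["ribotype"]).reindex(
        index=labels, columns=labels, fill_value=0
    )
    counts.index.name = "mitotype"
    counts.columns.name = "ribotype"
    return DiscordanceTable(counts=counts, assignments=rows)
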