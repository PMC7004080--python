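# divmig

Demographic inference of two-population divergence with gene flow from
the joint allele-frequency spectrum (AFS), plus the marker-level toolbox
used around such analyses in host–symbiont systems: sequence distances
and diversity, F_ST, recombination filtering, median-joining haplotype
networks, and host-mitotype × symbiont-ribotype discordance tables.

The motivating setting is a pair of deep-sea vesicomyid clam species
whose chemosynthetic bacterial symbionts are maternally cotransmitted
with the mitochondrion.  Individuals carrying one species' mitotype but
the other species' symbiont ribotype signal lateral symbiont transfer;
whether the host species hybridized in the past is a question about
divergence with gene flow, answerable from genome-wide SNPs.

## What it computes

Seven divergence scenarios are compared: strict isolation (SI),
isolation-with-migration (IM), ancient migration (AM), secondary contact
(SC), and the heterogeneous-introgression variants IM2M/AM2M/SC2M in
which a fraction *P* of the genome exchanges migrants at neutral scaled
rates (*M* = 2·N_ref·*m*) while the remainder uses reduced effective
rates (*Me*).  Sizes ν are relative to the ancestral N_ref, times are in
2·N_ref generations, and θ = 4·N_ref·µ·L scales the spectrum.

The expected spectrum entry is (θ/2)·E[L_ij] — the mean genealogy branch
length subtending i haplotypes of population 1 and j of population 2 —
estimated by a seeded Monte-Carlo structured-coalescent engine
(cross-validated against a discrete Wright–Fisher simulation and
msprime).  The observed folded spectrum is fit by a Poisson composite
likelihood with θ profiled analytically, optimized by hot/cold simulated
annealing followed by bounded refinement, and models are ranked by AIC
with Akaike weights exp(−ΔAIC/2) (normalized).  A seeded synthetic-data
module generates every input the pipeline consumes — SNP panels,
multi-locus Sanger-style alignments with a low-effective-size
mitochondrial locus, and symbiont labels with a configurable lateral
transfer probability — with ground truth recorded alongside.

## Worked example

Simulate 5,000 unlinked SNPs for 4 + 4 diploids under strict isolation,
build and fold the joint AFS, and ask whether SI or IM explains it:

```python
from divmig import (DemographicModelSpec, SimulationConfig, FitSettings,
                    afs_from_genotypes, model_selection,
                    simulate_snp_genotypes)

spec = DemographicModelSpec("SI", nu1=1.0, nu2=1.0, T_s=1.0)
cfg = SimulationConfig(model_spec=spec, n1=4, n2=4,
                       num_snp_sites=5000, seed=11)
geno, truth = simulate_snp_genotypes(cfg)
obs = afs_from_genotypes(geno).fold()
table = model_selection(
    obs, ["SI", "IM"],
    settings=FitSettings(n_runs=3, n_iters=120, engine_genealogies=1500,
                         engine_seed=77, seed=5),
)
print(table.to_frame()[["model", "Ln", "AIC", "AICw"]].to_string(index=False))
```

prints

```
model          Ln        AIC         AICw
   SI -147.875525 301.751050 1.000000e+00
   IM -345.316369 700.632738 2.420706e-87
```

SI carries essentially all the Akaike weight, as it should: the data
were simulated without gene flow, and IM's best runs drove migration to
the search bound and were filtered as spurious.  `Ln` is the Poisson
composite log-likelihood at the profiled θ; `AICw` is the relative
support among the candidates.

The same workflow is available from the shell:

```bash
divmig simulate --model SI --params params.json --sites 5000 --seed 11 --out sim/
divmig afs --genotypes sim/genotypes.tsv --out obs.fs
divmig fit --sfs obs.fs --models SI,IM,AM,SC,IM2M,AM2M,SC2M --out table.tsv
```

with further subcommands `stats` (diversity/F_ST per locus), `net`
(median-joining network to GML/TSV), `discordance` (mitotype × ribotype
cross-tabulation) and `run` (configured pipeline with a checksummed
provenance manifest).

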