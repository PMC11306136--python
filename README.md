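# cadnet

Systems-genetics pipeline for building a **tissue-specific molecular
interactome** and characterizing the subnetwork that connects genes carrying
disease-associated GWAS variants.  The package was written with coronary
artery disease (CAD) in mind — its defaults are the trait names, confidence
thresholds and expression rules appropriate for a coronary-artery analysis —
but every stage is a reusable, independently testable library function.

## What it does

1. **Seed-gene selection.**  A GWAS-Catalog-style association table is
   filtered to variants whose trait matches one of the target traits
   (default: *Coronary artery disease*, *Coronary heart disease*, *Ischemic
   heart disease*), whose consequence is protein-altering
   (`missense_variant`, `stop_gained`) and whose association p-value is
   `< 1e-5` (strict).  The unique mapped genes are the *seeds*.
2. **Interactome assembly.**  Scored protein–protein interaction edge lists
   are thresholded per source (STRING-like `> 0.7`, mentha-like `> 0.5`,
   IntAct-like `> 0.45`, strictly), merged with unscored BioGRID-style
   genetic/physical interactions, and pruned to genes expressed in the
   tissue (TPM `> 0` in at least 80% of samples, inclusive).
3. **Co-expression inference.**  Dependence between each seed and every
   other expressed gene is measured by plug-in mutual information on
   equal-frequency bins, `I(x,y) = S(x) + S(y) − S(x,y)` (nats).
   Significance at `p < 1e-15` — far below permutation resolution — is
   calibrated by fitting an exponential right tail,
   `ln P(MI ≥ m) = a + b·m`, to the permutation null and extrapolating.
4. **Shortest-path subnetwork.**  The union of *all* minimum-hop paths
   between every seed pair is extracted by unweighted BFS with a
   distance-criterion edge test (`d(s,u) + 1 + d(v,t) = d(s,t)`), avoiding
   explicit path enumeration; the most seed-rich connected component is
   kept.
5. **Hub topology.**  Degree and normalized betweenness are computed on the
   subnetwork; the top 1% by degree (`max(1, floor(0.01·n))`, i.e. 43 hubs
   on a 4,383-node subnetwork) are flagged, and hubs that are not seeds are
   reported separately.
6. **Over-representation.**  Subnetwork genes are tested against GMT gene
   sets by the upper-tail hypergeometric test, pooled Benjamini–Hochberg
   adjusted, significant at FDR `< 0.05` (strict).

A synthetic-data module generates all four inputs (expression with planted
latent-factor co-expression modules, catalog, scored PPI files, GMT
collections) with exact ground truth, so the entire pipeline is testable
offline.

## Worked example

```sh
cadnet simulate --outdir fixture --seed 1
cadnet run-all --config config.yaml        # paths pointing at fixture/
```

or in one Python call:

```python
from cadnet import FixtureConfig, write_fixture, PipelineConfig, run_pipeline

paths = write_fixture(FixtureConfig(rng_seed=1), "fixture")
config = PipelineConfig(
    catalog=str(paths["catalog"]), expression=str(paths["expression"]),
    edge_files={s: str(paths[s]) for s in ("string", "mentha", "intact", "biogrid")},
    gmt_files=[str(paths["gmt"])], outdir="out",
)
manifest = run_pipeline(config)
```

On the default fixture (300 genes × 240 samples, 6 seed genes planted in
two loading-0.95 co-expression modules, a non-seed bridge hub wired to all
seeds) this prints, via `manifest["stages"]`:

* 12 of 60 catalog rows pass the filters, mapping to **6 seed genes** —
  exactly the planted ground truth;
* 270 of 300 genes pass the expression rule; the merged interactome has
  **268 nodes and 711 edges** (PPI + co-expression);
* the MI cutoff at `p < 1e-15` is ≈ **1.06 nats**; all 66 planted
  seed–partner module pairs are recovered as co-expression edges (100%);
* the shortest-path subnetwork contains the 6 seeds plus the planted bridge
  gene, which surfaces as the top-degree hub despite not being a seed —
  the same phenomenon that makes non-seed connector hubs biologically
  interesting;
* both planted gene sets are significant at FDR < 0.05 and no decoy set is.

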