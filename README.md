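# wormnet

Co-occurrence network and keystone-taxon analysis for paired earthworm-gut /
soil microbiome studies.

Earthworm guts host bacterial communities assembled from the surrounding
soil, and a small set of highly connected "keystone" taxa appears to
organise both community structure and carbon metabolism across the two
habitats. `wormnet` implements the statistical pipeline used to make that
argument, for anyone who has an OTU count table, sample metadata and
(optionally) Biolog plate readings from a paired-habitat design:

- **Community**: rarefaction (multivariate hypergeometric, seeded), alpha
  diversity (Shannon *H* in nats, classic Chao1, richness, Pielou
  *J* = *H*/ln *S*), shared/unique OTU partitions between habitats, one-way
  ANOVA with Tukey HSD and compact-letter displays.
- **Network**: OTUs present in more than two-thirds of samples are
  correlated all-against-all (Spearman mid-rank ρ on relative abundances);
  edges are kept when |ρ| > 0.8 and the Benjamini–Hochberg adjusted
  *q* < 0.01. Modules come from Newman-modularity maximization
  (*Q* = Σ_s (e_ss − a_s²)): exact enumeration on tiny graphs, deterministic
  greedy agglomeration with node-move refinement otherwise.
- **Keystone**: per-node within-module degree z-score Zi and participation
  coefficient Pi = 1 − Σ_s (k_is/k_i)². Module hubs (Zi > 2.5, Pi ≤ 0.62),
  connectors (Zi ≤ 2.5, Pi > 0.62) and network hubs (both high) form the
  keystone set. A removal test deletes the keystones, re-detects modules and
  compares the modularity drop against random same-size removals
  (empirical *p*). Keystone abundances are screened against environmental
  covariates (pH, OM, TN, TP, TK, MC) and AWCD with Spearman + BH.
- **Metabolism**: Biolog plate OD590 time series and average well colour
  development, AWCD(t) = (1/n) Σ_i max(OD_i(t) − OD_control(t), 0), overall
  and per carbon-source category.
- **Synthetic data**: a generator that emulates the 4-group study design
  (HMs/HMe/HMLs/HMLe, 24 samples) with planted correlation modules, hub
  taxa, a gut diversity deficit, environment-coupled abundances and
  per-group Biolog growth curves — so every stage of the pipeline is
  testable against known ground truth.

## Worked example

```python
from wormnet import (SimulationConfig, generate_community, prevalence_filter,
                     build_network, detect_modules)
from wormnet.keystone import zi_pi, keystones_of, removal_stability
from wormnet.synthetic_data import module_recovery_ari, hub_recall

cfg = SimulationConfig(seed=7)                    # 24 samples, 300 taxa,
table, meta, truth = generate_community(cfg)      # 4 planted modules, 8 hubs
net = build_network(prevalence_filter(table))     # r > 0.8, q < 0.01
part = detect_modules(net)
topo = zi_pi(net, part)                           # Zi-Pi roles per node
keys = keystones_of(topo)
stab = removal_stability(net, keys, n_null=199, seed=7)
```

This prints (via the obvious f-strings):

```
network: 286 nodes, 1680 edges, Q = 0.690 in 31 modules
keystones: 7 taxa -> ['OTU_001', 'OTU_002', 'OTU_071', 'OTU_072'] ...
module recovery ARI = 0.990, hub recall = 0.88
removal test: Q 0.690 -> 0.678, p = 0.050
```

Reading: the prevalence filter keeps 286 of 300 taxa; the thresholded
Spearman network has 1,680 edges and a modular structure (Q = 0.69; most of
the 31 "modules" are isolated-node singletons around the 4 real blocks).
Seven nodes are called keystones, recovering 7 of the 8 planted hubs; the
detected modules match the planted ones almost perfectly (adjusted Rand
index 0.99). Deleting the keystones degrades modularity more than 95% of
random same-size deletions (empirical p = 0.05 at its resolution limit of
1/200).

The same pipeline runs from the shell on TSV/CSV inputs:

```sh
wormnet simulate --out demo --seed 7
wormnet run-all --table demo/otu_table.tsv --metadata demo/metadata.tsv \
    --biolog demo/biolog.csv --truth demo/truth.json --out demo/run --seed 7
```

which writes `demo/run/report.json` plus per-stage TSV/GraphML artifacts.
Rerunning with the same config is byte-identical.

## Layout

```
src/wormnet/
  community.py       OTU table, I/O, rarefaction, diversity, Venn, Tukey
  network.py         Spearman + BH thresholding, modularity, module detection
  keystone.py        Zi-Pi, roles, removal stability, env correlation
  metabolism.py      Biolog plates and AWCD
  synthetic_data.py  seeded generator with planted ground truth
  pipeline.py        run-all orchestration, validation, report
  cli.py             `wormnet` command-line interface
docs/methods.md      model assumptions, defaults, numerical choices
```
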