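# triweb

Structure and robustness of **tripartite ecological networks** — communities
in which three species sets are joined by two bipartite interaction layers
that share one set. Examples: plants shared by pollinators and herbivores
(a *fan*: the shared set is the resource of both layers), or herbivores
sitting between plants and parasitoids (a *chain*). The sign pair of the two
layers classifies a network as mutualism–mutualism (MM),
mutualism–antagonism (MA) or antagonism–antagonism (AA).

The package is for ecologists who want to ask, on such two-layer webs:

* How are the layers stitched together? Via the **connector nodes** — the
  shared species with links in both layers — summarized by the connector
  proportion *C*, the hub–connector proportion *H_C* (fraction of the top
  20% shared species by degree that connect), and the mean **participation
  coefficient** of connectors, *PC* = 2·k_min/k_tot (1 = links split evenly
  between layers).
* How robust is the community to plant loss? Plants are removed in an
  *extinction sequence*; animals are under bottom-up control and go extinct
  when they lose all resource links (simultaneous losses in fans, cascading
  losses in chains). The **robustness** *R* is the area under the curve of
  surviving animal fraction versus fraction of plants removed; per-set
  variants (*R_P*, *R_H*) and the robustness of the two standalone bipartite
  networks (*R_L*, *R_S*, larger/smaller) are also computed, plus a
  stochastic variant in which losing resource *j* kills consumer *i* with
  probability *R_i · d_ij* (intrinsic dependence × dependency weight).
* Do the two animal sets rise and fall together? The **interdependence**
  *I* is the correlation, across random sequences, of the two sets'
  robustness.
* Which plants matter most? **Plant importance** correlates each plant's
  position in the sequence with the resulting community damage; whether one
  layer's ranking drives the whole-community ranking is classified
  driven / mixed / emergent via *S_set*, the squared rank correlation.
* Is an observed structure surprising? Four **null models** of increasing
  constraint (fixed sizes and link counts → fixed consumer degrees → fixed
  degree multisets with broken cross-layer correlation → exact per-node
  degrees via edge swaps) give z-scores for any statistic.

A synthetic-network generator with tunable sizes, degree distributions,
connector fraction and participation targets stands in for empirical data
sets, so every analysis is runnable and testable end to end.

## Worked example

```python
import numpy as np
import triweb as tw

net = tw.generate(tw.GeneratorConfig(sizes=(40, 40, 40),
                                     target_C=0.35, target_PC=0.6, seed=1))
m = tw.structural_metrics(net)
print(f"class      : {tw.classify_network(net).value}")
print(f"C          : {m.C:.3f}")
print(f"PC_C       : {m.PC_C:.3f}")

ens = tw.run_ensemble(net, n=1000, seed=2)
print(f"mean R     : {ens.series('whole').mean():.3f}")
print(f"I (pearson): {tw.interdependence(ens).I:.3f}")
print("top 3      :", tw.plant_importance(ens, 'whole').ranking()[:3])

cmp2 = tw.null_compare(net, "PC_C",
                       tw.NullModelSpec(model=2, n_replicates=100, seed=3))
print(f"null 2 PC_C: obs={cmp2.observed:.3f} "
      f"null={cmp2.null_mean:.3f}+/-{cmp2.null_sd:.3f} z={cmp2.z:.2f}")
```

prints

```
class      : MA
C          : 0.350
PC_C       : 0.592
mean R     : 0.554
I (pearson): 0.119
top 3      : ['p02', 'p15', 'p05']
null 2 PC_C: obs=0.592 null=0.743+/-0.034 z=-4.40
```

Reading: the generator hit its structural targets (35% of plants are
connectors, with links moderately split between layers). Random plant loss
leaves an area of 0.554 under the survivor curve; the two animal sets'
robustness are nearly uncorrelated (*I* ≈ 0.12), so sequences benign for one
set need not be benign for the other. Plant `p02` is the strongest keystone
candidate. Under null model 2 (consumer degrees kept, plant attachments
randomized) the connectors' participation is markedly *lower* than chance
(z ≈ −4.4): the realized layer split is more uneven than degree structure
alone would produce.

The same pipeline is available from the shell:

```bash
triweb synth config.yaml -o net.tsv
triweb metrics net.tsv
triweb robustness net.tsv -n 3000 --seed 1 -o runs.csv --summary summary.json
triweb interdependence runs.csv
triweb importance runs.csv --scope whole
triweb nullmodel net.tsv --model 2 --statistic PC_C -r 100 --seed 3
```

Networks travel as an edge-list TSV (`layer  resource  consumer
[weight]`) plus a small YAML metadata file naming the three species sets and
each layer's sign and orientation; incidence-matrix CSVs are also read.

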