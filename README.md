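# wisentpanel

A tested, reusable implementation of the reduced SNP-panel workflow for
non-invasive genetic monitoring of European bison (*Bison bonasus*).

Conservation management of the wisent — a species rebuilt from roughly a
dozen founders and managed in two breeding lines, the lowland line (LL) and
the lowland–Caucasian line (LC), with gene flow tolerated only from LL into
LC — increasingly relies on genotyping hair, faeces and other non-invasive
samples on a small panel of ~96 biallelic SNPs. Such samples are genotyped in
replicates, and everything downstream depends on how those replicates are
condensed into a consensus genotype and how the residual error is
quantified. This package implements the full chain:

- **Consensus genotyping** from replicate call tables by fixed precedence
  rules, with decomposition of genotyping error into allelic dropout
  (ADO: a heterozygote read as a homozygote) and false alleles (FA: an
  allele absent from the consensus), per-locus and per-sample rates, call
  rates, and locus-exclusion flagging.
- **Sex determination** from a Y-associated marker by majority vote over
  replicates (4/6 spurious Y calls → male false positive, 3/6 →
  undetermined — the observed failure modes of replicated Y-cluster FAs).
- **Individual identification**: cumulative probability-of-identity curves
  for unrelated individuals and full siblings,
  PID_l = Σp_i⁴ + Σ_{i<j}(2p_i p_j)² and
  PIDsib_l = 0.25 + 0.5Σp_i² + 0.5(Σp_i²)² − 0.25Σp_i⁴,
  multiplied over loci sorted by descending H_E; pairwise allele-mismatch
  matching with same-individual grouping.
- **Parentage**: pairwise Mendelian exclusion (opposing homozygotes) plus a
  single-parent LOD score with per-locus error rate ε = 1e-4, and
  reconciliation of assigned parent–offspring links against a studbook
  pedigree (verified / not-verified / not-testable / novel).
- **Marker selection**: chi-square HWE tests, composite LD (R² of dosage
  vectors) with greedy pruning, per-locus Nei FST between lines
  ((H_T − H_S)/H_T; Weir–Cockerham θ optional), private alleles, and the
  line-discrimination subset at FST ≥ 0.075, all on a
  first-degree-relative-free reference set.
- **Breeding-line assignment** by two independent methods — classification
  EM under a HWE-within-cluster likelihood with BIC over a K grid, and
  supervised leave-one-out Dirichlet(1) assignment — combined by a dual
  rule: assign a line only if both methods give it ≥ 60%.
- **Cross-species detection**: call-rate gating (≥ 80%) and PCoA of the
  codominant squared genetic distance (0/1/4 per locus, rescaled for
  missingness).
- **Genetic diversity**, molecular and pedigree side by side: H_O, unbiased
  H_S/uH_E, H_T, rarefied allelic richness, F_IS/F_ST/F_IT in two averaging
  modes; kinship by the tabular method, inbreeding, gene diversity of the
  living gene pool from mean kinship and from gene drop, founder
  contributions, and pedigree F-statistics.

A first-class synthetic-data module simulates the whole setting — the
12-founder bottleneck, the nested two-line split with one-directional gene
flow, Mendelian gene dropping over unlinked loci, and a replicate
observation model with per-call ADO/FA/missingness (defaults 1.6% / 0.3% /
solved for 92.4% non-invasive and 98% invasive call rates) plus an event
log — so every stage is testable without any external data.

## Worked example

```python
import numpy as np
from wisentpanel import simulate as sim, consensus as cns, identity as idn, panel_io as pio

cfg = sim.SimConfig(seed=42)
truth = sim.simulate_population(cfg)

# genotype the sampled population: the living plus their recorded parents
ped = truth.pedigree
living = list(ped.table.index[ped.table["alive"]])
parents = {p for i in living for p in ped.parents(i) if p is not None}
sampled = sorted(set(living) | parents)
rcs, _ = sim.observe_replicates(truth, cfg, individuals=sampled)

panel = pio.default_panel()
gm, results = cns.consensus_matrix(rcs, panel)
report = cns.estimate_error_rates(rcs, results, panel)
r = report.conditional_rates
print(f"samples genotyped: {len(gm.individuals)}")
print(f"mean consensus call rate: {np.mean([c.call_rate for c in results]):.3f}")
print(f"ADO rate: {100*r['ado']:.2f}%  FA rate: {100*r['fa']:.2f}%  GE rate: {100*r['ge']:.2f}%")

freqs = idn.allele_frequencies(gm, pio.subset(panel, "individualisation"))
curve = idn.pid_curves(freqs)
print(f"PID <= 1e-4 after {curve.loci_to_pid} loci; PIDsib <= 1e-4 after {curve.loci_to_pidsib} loci")
```

Output:

```
samples genotyped: 493
mean consensus call rate: 0.999
ADO rate: 1.75%  FA rate: 0.27%  GE rate: 2.02%
PID <= 1e-4 after 10 loci; PIDsib <= 1e-4 after 18 loci
```

Reading: 493 individuals were consensus-genotyped from triplicate
non-invasive (and single-replicate invasive) observations; replication
rescues almost all per-replicate missingness, so the consensus call rate is
near 1 even though each replicate has ~92% calls. Scoring every replicate
against its consensus recovers the simulated error process — ADO near 1.6%
of heterozygous-genotype comparisons, FA near 0.3% of homozygous ones. Ten
of the most heterozygous loci suffice to push the probability that two
random wisent share a multilocus genotype below 1e-4, eighteen for the
stricter full-sibling bound — which is why a 96-SNP panel is comfortable for
individualisation in this low-diversity species.

The same stages are available from the command line:

```sh
wisentpanel simulate --seed 42 --out run/
wisentpanel consensus run/call_table.csv --out run/cons/
wisentpanel identify run/cons/consensus_genotypes.csv --out run/ident/
wisentpanel parentage run/cons/consensus_genotypes.csv --pedigree run/pedigree.csv --out run/po/
wisentpanel select-markers run/true_genotypes.csv --pedigree run/pedigree.csv --out run/sel/
wisentpanel assign-lines run/true_genotypes.csv --out run/lines/
wisentpanel species run/true_genotypes.csv --out run/species/
wisentpanel diversity run/true_genotypes.csv --pedigree run/pedigree.csv --out run/div/
```

Each subcommand writes CSV results plus a `run_summary.json`; thresholds and
seeds can be set in a YAML config passed with `--config`.

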