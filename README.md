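# pedsight

Genealogical analysis of pedigreed populations — the toolkit a conservation
geneticist or studbook keeper needs to turn a pedigree table into the
standard battery of gene-origin and inbreeding statistics. It was built
around the demands of closed captive-bred populations such as the European
bison (wisent) studbook: a handful of founders, two partially overlapping
breeding lineages, overlapping generations across more than a century, and
strong male reproductive skew.

## What it computes

Given a pedigree (one row per animal: id, sire, dam, sex, dates, optional
lineage) and a reference population (the living animals at a census date):

* **Pedigree completeness** — maximum traced generations, complete
  generations, complete generations equivalent
  (CGE = Σ over known ancestors of (1/2)^g), and the pedigree completeness
  index (PCI, harmonic mean of paternal/maternal ancestor knowledge over
  *d* generations).
* **Inbreeding and relatedness** — individual inbreeding coefficients *F*
  by the Meuwissen–Luo ancestor-tracing algorithm; average relatedness
  AR_i = mean of row *i* of the numerator relationship matrix **A**,
  computed matrix-free (Colleau's indirect method) so studbook-scale
  pedigrees never materialise **A**; explicit kinship submatrices for small
  subsets.
* **Ancestral vs. new inbreeding** — gene-dropping (Monte Carlo or exact
  enumeration) partitions *F* into first-time identity-by-descent (F_new)
  and IBD involving alleles already exposed to inbreeding in ancestors
  (F_a-Kal, Kalinowski), plus Ballou's ancestral inbreeding.
* **Probability of gene origin** — founder contributions p_i and the
  effective number of founders f_e = 1/Σp_i²; Boichard's greedy marginal
  contributions and the effective number of ancestors f_a; founder genome
  equivalents f_ge = 1/(2·mean coancestry); and the genetic-diversity loss
  partition 1−GD = 1/(2 f_ge) split into founder-imbalance loss
  1−GD* = 1/(2 f_e) and drift loss.
* **Demography** — generation intervals over the four sexed
  parent–offspring paths and reproductive-skew summaries.
* **Effective population size** — from the regression of *F* on CGE
  (N_e = 1/2b) and from the individual increase in inbreeding
  ΔF_i = 1 − (1−F_i)^(1/(t_i−1)), N_e = 1/(2·mean ΔF).
* **Wright's F-statistics** — F_IS, F_ST, F_IT for a lineage-partitioned
  reference set from mean coancestries (Caballero–Toro formulation), with
  (1−F_IT) = (1−F_IS)(1−F_ST) holding as an identity.

A forward simulator (`pedsight.synthetic_data`) generates studbook-like
pedigrees with known ground truth (exact founder shares and *F*), so every
statistic can be validated against truth without external data.

## Worked example

```python
import pedsight as ps

ped, truth = ps.simulate_pedigree(
    ps.SimConfig(seed=7, missing_parent_rate=0.03, missing_sex_rate=0.01))
ref = ps.select_reference(ped, "2060-12-31")      # alive at the census date
origin = ps.gene_origin_summary(ped, ref)
print(f"fe={origin.fe:.2f} fa={origin.fa:.2f} fge={origin.fge:.2f} "
      f"n50={origin.n50} loss={100*origin.loss_total:.2f}%")
```

prints

```
fe=11.28 fa=10.59 fge=3.91 n50=4 loss=12.79%
```

i.e. the simulated reference population behaves like one descended from
about 11 equally-used founders, only four ancestors explain half its gene
pool, and 12.79 % of founder gene diversity has been lost (4.43 % from
unequal founder use, the rest from drift). The same pedigree yields an
individual-increase effective size near 25:

```python
import numpy as np
from pedsight.completeness import completeness_table
comp = completeness_table(ped)
F = ps.inbreeding_meuwissen_luo(ped)
mask = np.isin(ped.ids, list(ref.ids))
ne = ps.ne_estimates(F, comp["cge"], comp["max_gen"], mask)
print(round(ne["individual-delta-F"].ne, 2))   # 24.94
```

The command-line interface mirrors the library:

```bash
pedsight simulate --seed 7 --out ped.csv --truth truth.tsv
pedsight inbreeding ped.csv --out inb.tsv
pedsight origin ped.csv --out origin.json
pedsight report ped.csv --partition lineage --out report/
```

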