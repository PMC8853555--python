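# akit — allele-frequency admixture inference

`akit` detects and quantifies gene flow between populations from
genome-wide SNP genotypes, the problem faced when, for example, South
Asian ancestry must be demonstrated and measured in Southeast Asian
populations.  It is aimed at population geneticists working with
genotyping-array data (EIGENSTRAT or PLINK binary) for tens of labelled
populations, and implements the complete f-statistics tool chain as a
tested, reusable Python library with a command-line front end.

## What it computes

All methods rest on three statistics of population allele frequencies
*p*:

- **f2(A,B) = E[(p_A − p_B)²]** — drift distance between two
  populations, additive along the branches of a population tree;
- **f3(X;A,B) = E[(p_X − p_A)(p_X − p_B)]** — with an outgroup X, the
  shared drift of A and B; significantly negative values mark X as
  admixed;
- **f4(A,B;C,D) = E[(p_A − p_B)(p_C − p_D)]** — zero when the pairs
  (A,B) and (C,D) are phylogenetically unconnected; the currency of all
  model tests.

Estimates carry sample-size bias corrections and standard errors from a
weighted delete-one block jackknife over contiguous genomic blocks
(default width 0.05 Morgans).  On top of these, `akit` provides:

- **Rank tests (qpWave-style)** — the f4 matrix between a "left" set of
  populations and a "right" reference set has rank at most r−1 when the
  left set descends from r ancestry streams; the generalized
  least-squares rank test yields a chi-squared p-value.  Rank 0 of a
  two-population left set is a test of cladality.
- **Admixture proportions (qpAdm-style)** — weights expressing a target
  as a mixture of 1–3 source surrogates, with jackknife standard errors
  and the two-criterion plausibility filter (model p ≥ 0.05 and every
  weight ± 2 SE inside [0,1]).
- **Admixture-graph fitting (qpGraph-style)** — given a rooted graph
  topology with drift edges and pulse admixture nodes, fits branch
  lengths (non-negative least squares) and admixture weights
  (multi-start bounded optimization) against the observed f2/f3 basis
  under its jackknife covariance, and reports a log-likelihood score and
  the worst f4 residual in SE units.
- **Exhaustive target mapping** — attaches a new population to every
  combination of 1–3 skeleton edges (E candidate edges give
  E + C(E,2) + C(E,3) models; 33 edges give 6,017), discards models with
  zero-length backbone edges (trifurcations), and selects across
  admixture counts by the 10-log-unit / 0.5-SE rules with 3-log-unit
  ties within a count.  Iterating this one population at a time grows a
  skeleton graph.
- **A drift simulator** — genotypes generated under a known admixture
  graph (Balding–Nichols Beta drift, binomial diploid sampling,
  missingness) with closed-form expected f-statistics, so every stage of
  the pipeline is validated against known truth.

## Worked example

Simulate genotypes from the bundled 11-leaf preset graph in which the
`Target` population draws 30% of its ancestry from the South Asian-like
lineage, then estimate the mixture:

```sh
akit simulate --out demo --n-snps 8000 --seed 5 --sas-fraction 0.3
akit qpadm demo --target Target --sources EastAsian4,SouthAsian \
    --right Outgroup1,African,Papuan,WestEurasian,EastAsian1,HunterGatherer
```

prints

```
source	weight	se
EastAsian4	0.7070	0.0298
SouthAsian	0.2930	0.0298
p = 0.8771; plausible = True
```

i.e. the target is modeled as 70.7 ± 3.0% East Asian-like and
29.3 ± 3.0% South Asian-like ancestry — within one standard error of the
generating 70/30 split — and the two-source model is not rejected
(p = 0.88), so it passes both plausibility criteria.  The same run
through the library:

```python
from akit import genio, waveadm

G = genio.read_genotypes("demo", "eigenstrat")
F = genio.pop_freqs(G)
blocks = genio.assign_blocks(G.snps, 0.05)
S = waveadm.build_f4_system(
    F, ["Target", "EastAsian4", "SouthAsian"],
    ["Outgroup1", "African", "Papuan", "WestEurasian", "EastAsian1",
     "HunterGatherer"], blocks)
model = waveadm.fit_qpadm(S)   # model.weights, model.weight_se, model.p_value
```

Graph mapping works the same way: `akit mapgraph` fits every attachment
of a target onto a skeleton graph file and reports the retained models;
`akit fitgraph` fits a single topology; `akit skeleton` grows a graph
population by population.

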