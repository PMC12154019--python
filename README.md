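# cannatype

Chemotype classification and THCAS/CBDAS allele-specific marker analysis
for *Cannabis sativa*.

## The problem

*Cannabis sativa* falls into three chemical phenotypes defined by its two
major cannabinoids: **chemotype I** (drug type, THC ≫ CBD), **chemotype II**
(intermediate, THC ≈ CBD) and **chemotype III** (fiber type, CBD ≫ THC).
Chemotyping requires mature female inflorescences and chromatographic
quantitation; genotyping the two synthase genes that control the phenotype —
*THCAS* (tetrahydrocannabinolic acid synthase) and *CBDAS* (cannabidiolic
acid synthase) — works on DNA from any tissue at any developmental stage.
`cannatype` implements both routes and quantifies their agreement:

* **Chemotype** from quantitation: the statistic is
  `x = log10(%THC / %CBD)` on percent dry-weight contents, with fixed
  cutoffs `x > 0 → I`, `−1 < x ≤ 0 → II`, `x ≤ −1 → III`; a
  complete-linkage Euclidean clustering of the log₁₀-transformed
  (%THC, %CBD) points is provided as the heatmap-style alternative.
* **Genotype** from sequence: an in-silico PCR engine simulates
  allele-specific (ARMS) multiplex assays whose primers place their
  3′-terminal base on the SNPs that distinguish active from inactive
  synthase alleles (*THCAS* CDS position 1349, *CBDAS* position 645),
  with internal-control amplicons per gene.  Band presence is coded
  `T/t` and `D/d`; composites map `Td → I`, `TD → II`, `tD → III`.
* **Sequence-level corroboration**: ORF-integrity analysis (premature
  stops, frameshifting indels such as the 4-bp deletion near *CBDAS*
  position 153 in drug-type alleles) and neighbor-joining phylogenies of
  single-gene and concatenated alignments, with column-resampling
  bootstrap, recovering the four activity clades (active/inactive ×
  THCAS/CBDAS).
* **Concordance**: a per-sample match table and the headline accuracy.

The package ships the published 85-sample survey table (46 cultivars, with
%THC, %CBD, reported log-ratios, chemotypes and wet-lab genotype letters)
and a synthetic-panel generator that emulates the survey's genetic
architecture, so every stage runs and is testable with no downloads.

## Worked example

Run the whole pipeline on a synthetic panel shaped like the survey
(70 drug / 11 intermediate / 4 fiber samples):

```bash
$ cannatype full --seed 42 --out run_demo
samples: 85
matches: 85 (100.0%)
chemotype counts: I=70, II=11, III=4
genotype counts:  TD=11, Td=70, tD=4
```

Every sample's marker-predicted chemotype agrees with its
quantitation-based chemotype (100%, 85/85), the behaviour the marker panel
is designed to have.  `run_demo/` contains the per-stage artifacts
(`sequences.fasta`, `cannabinoids.csv`, `bands.csv`, `genotype.csv`,
`chemotype.csv`, `concordance.csv`) plus `manifest.json` recording the
seed and parameters that regenerate the run byte-identically.

From Python, on the packaged survey table:

```python
>>> from cannatype import datasets, chemotype
>>> records = datasets.reference_records()
>>> calls = chemotype.classify_records(records)
>>> sorted({c.chemotype for c in calls})
['I', 'II', 'III']
>>> sum(c.chemotype == "II" for c in calls)
11
>>> round(chemotype.compute_log_ratio(records[1])[0], 3)  # sample TK2
1.175
```

The value 1.175 is TK2's log₁₀(%THC/%CBD) = log₁₀(0.928/0.062): well above
the 0.0 cutoff, a drug-type call.

## Layout

* `src/cannatype/chemotype.py` — log-ratio statistic, fixed cutoffs, clustering
* `src/cannatype/pcr.py` — in-silico ARMS PCR engine
* `src/cannatype/genotype.py` — band → allele → composite → predicted chemotype
* `src/cannatype/orf.py` — translation, frameshift/truncation, activity calls
* `src/cannatype/phylo.py` — star alignment, JC69 distances, NJ, bootstrap
* `src/cannatype/concordance.py` — chemotype/genotype agreement
* `src/cannatype/synthetic.py` — synthetic panel generator and fixtures
* `src/cannatype/cli.py` — the `cannatype` command
* `docs/methods.md` — models, parameters, design choices and limitations
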