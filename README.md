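# dompred

Protein function prediction from domain–protein–function tripartite networks.

Most proteins carry structural domains (e.g. CATH-Gene3D homologous
superfamilies or FunFams) whose presence is strongly informative about
molecular function, pathway membership and localisation. `dompred` exploits
this by building a three-layer network — domains, proteins, functional terms
(GO, KEGG, Reactome or any other vocabulary) — in which proteins mediate every
domain–function relation, scoring how strongly each domain's protein
neighbourhood overlaps each function's, and transferring those associations to
query proteins through their domain content. It is aimed at computational
biologists who need function predictions for proteins that have domain
assignments but sparse experimental annotation, and who want a benchmarkable,
fully scriptable pipeline.

## Model

For a domain *D* and function *F*, let *N<sub>p</sub>(D)* and *N<sub>p</sub>(F)*
be the protein sets connected to each node and *n<sub>T</sub>* the number of
protein nodes. Four association indices are available:

- Jaccard: |N<sub>p</sub>(D) ∩ N<sub>p</sub>(F)| / |N<sub>p</sub>(D) ∪ N<sub>p</sub>(F)|
- Simpson: |N<sub>p</sub>(D) ∩ N<sub>p</sub>(F)| / min(|N<sub>p</sub>(D)|, |N<sub>p</sub>(F)|)
- PCC (phi coefficient): (|∩|·n<sub>T</sub> − |N<sub>p</sub>(D)|·|N<sub>p</sub>(F)|) / √(|N<sub>p</sub>(D)|·|N<sub>p</sub>(F)|·(n<sub>T</sub>−|N<sub>p</sub>(D)|)·(n<sub>T</sub>−|N<sub>p</sub>(F)|))
- HyI: −log₁₀ of the upper-tail hypergeometric probability of the observed
  overlap (an over-representation test statistic)

For a query protein, every function supported by at least one of its domains
receives a combined score over the *k* contributing domains: Jaccard, Simpson
and PCC values are z-standardised over the association table,
*z = (a − ā)/s*, and combined with Stouffer's method, *Z = Σzᵢ/√k* (PCC in
absolute value); HyI values are converted to p-values, *p = 10^(−HyI)*, and
combined with Fisher's method, *X = −2Σln pᵢ ~ χ²₂ₖ*. Combined scores are
normalised into (0, 1] — Stouffer scores re-standardised, clipped to ±2 and
mapped through *z/4 + 0.5*; Fisher p-values mapped to *1 − p* — and scores
below 0.001 are discarded.

Evaluation implements protein-centric **Fmax** (maximum harmonic mean of
protein-averaged precision and recall over a 0.01-step threshold grid),
**Smin** (minimum semantic distance weighted by per-term information
accretion), **coverage**, full/partial modes, a frequency ("naive") baseline,
and a pooled self-prediction precision–recall procedure that works for any
annotation vocabulary (GO, KEGG, Reactome, ...).

## Worked example

Generate a 500-protein synthetic corpus with 10% annotation noise, score
Simpson associations, predict, and evaluate by self-prediction:

```bash
dompred simulate --n-proteins 500 --noise-rate 0.1 --seed 42 --out-dir sim
dompred associate --domains sim/protein_domains.tsv \
    --functions sim/protein_functions.tsv --metric simpson --out associations.tsv
# -> 659 associations (mean=0.1728, std=0.2268)
dompred predict --domains sim/protein_domains.tsv --associations associations.tsv \
    --metric simpson --combiner stouffer --out predictions.tsv
# -> predicted 500 proteins (7868 records), 0 unpredictable
dompred evaluate-ppp --predictions predictions.tsv \
    --annotations sim/protein_functions.tsv --out report.json
# -> fmax    0.929637526652452
# -> auc_pr  0.8976582396042198
```

The corpus plants one function per domain, so each protein's true functions
are determined by its domains; with 10% of annotation edges redirected to
random functions, ranking all 7,868 scored (protein, function) pairs by
normalised score still recovers the planted annotation with a maximum
F-measure of 0.93 and an area under the precision–recall curve of 0.90. At
zero noise both reach 1.0. The same stages accept real annotation files: tab
separated `protein<TAB>domain` and `protein<TAB>function[<TAB>evidence]`
pairs, with optional evidence filtering (`--exclude-evidence IEA`) and an OBO
ontology for propagation and Smin (`dompred evaluate-cafa --obo go.obo ...`).
A YAML config can drive the whole pipeline at once: `dompred run --config
config.yaml --seed 1 --out-dir run/`.

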