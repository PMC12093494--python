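# cazprofiler

Comparative genomics of carbohydrate-active enzymes (CAZymes) from HMMER
domain tables.

Microbial genomes are routinely screened for CAZymes — glycoside hydrolases
(GH), glycosyltransferases (GT), polysaccharide lyases (PL), carbohydrate
esterases (CE), auxiliary activities (AA) and carbohydrate-binding modules
(CBM) — by scanning predicted proteomes against a profile-HMM database such
as dbCAN with `hmmscan --domtblout`. Turning those raw domain tables into
comparative biology takes a series of well-defined steps, which this package
implements as a tested, reusable library and command line tool:

1. **Parse** domtblout files bit-exactly, computing each hit's covered
   fraction of the HMM profile, `(hmm_to − hmm_from + 1) / hmm_length`.
2. **Filter** low-quality hits (coverage ≥ 0.35; i-Evalue ≤ 1e−15, relaxed
   to 1e−3 for alignments under 80 residues) and **resolve overlapping
   redundant hits** greedily by independent e-value, allowing at most 50%
   overlap of the shorter alignment interval. All thresholds configurable.
3. **Build domain architectures** — the retained domains of each protein in
   sequence order (`GH23+CBM50+CBM50`) — and classify each protein's
   combinatorial pattern: a domain *alone*, in *multiple copies*, or *with
   accessory* domains; tally family co-occurrence at protein level.
4. **Profile organisms**: %CAZyme CDS (`100 · cazyme_cds / total_cds`),
   protein counts per category, per family, and per degradable
   polysaccharide substrate (cellulose, xylan, lignin, starch, chitin,
   dextran, fructan, pectin) through a curated substrate → family map that
   handles bifunctional families (GH13 acts on both starch and dextran) and
   subfamily inheritance.
5. **Compare groups**: medians/SDs/quartiles by suborder, family or
   habitat; pairwise Welch's t-tests; OLS regression R²; covariance PCA of
   the organisms × 6 category count matrix.

A synthetic-data generator produces full benchmark datasets — taxonomy,
metadata, domtblout files with planted architectures plus overlap and
low-coverage decoys — with exact ground truth, so the entire pipeline is
testable end to end without downloads.

## Worked example

```sh
# generate a synthetic 61-organism study and analyse it
cazprofiler simulate --out run/dataset --seed 1
cazprofiler all --input-dir run/dataset/domtblout \
    --metadata run/dataset/metadata.tsv --out run/results
```

or, in Python:

```python
from cazprofiler import (SimConfig, generate_dataset, RunConfig, run_pipeline)
import pandas as pd

ds = generate_dataset(SimConfig(seed=1), outdir="run/dataset")
out = run_pipeline(RunConfig(input_dir="run/dataset/domtblout",
                             metadata_path="run/dataset/metadata.tsv",
                             output_dir="run/results"))
prof = pd.read_csv(out / "profiles.tsv", sep="\t")
print(prof.groupby("suborder")["pct_cazyme"].median().round(2))
```

```
suborder
Cystobacterineae    3.82
Nannocystineae      2.02
Sorangiineae        3.21
```

Each organism devotes roughly 2–5% of its coding sequences to CAZymes; the
soil-dwelling Cystobacterineae and Sorangiineae sit near 3–4% while the
marine Nannocystineae are lowest, and `welch_tests.tsv` shows the pairwise
Welch p-values behind those contrasts (Cystobacterineae vs Nannocystineae
p ≈ 5e−08 in this run). `regression.tsv` reports R² ≈ 0.96 for total CDS
against genome size, and `pca_variance.tsv` the variance shares of the six
category counts. The output directory also contains the filtered hits,
architectures, pattern/co-occurrence tables, per-family and per-substrate
count matrices, and a `manifest.json` with SHA-256 checksums proving the
run is a pure function of its inputs.

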