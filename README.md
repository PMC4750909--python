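# oligocoi

COI metabarcoding analysis of mixed aquatic-oligochaete samples:
paired-read filtering, OTU delineation, PCR-bias correction and the IOBS
sediment-quality index.

Aquatic oligochaetes are sensitive bioindicators of freshwater sediment
quality, but morphology-based species identification is impractical in
routine monitoring (most specimens are immature; several morphospecies hide
cryptic diversity). Metabarcoding the standard ~658 bp mitochondrial COI
barcode from pooled specimens offers a way out — if read abundances can be
related back to specimen abundances despite strong, taxon-specific PCR
amplification bias. This package implements that analysis end to end for
experiments in which every specimen of a mixed sample is also Sanger
sequenced, so the true community composition is known:

1. **Read processing** (`oligocoi.reads`) — non-overlapping 2x251 bp read
   pairs are kept only when both mates have mean Phred quality >= 30 with at
   most one base below Q30; orientation is resolved by locating the HCO2198
   primer in R1 and then LCO1490 in R2 (or vice versa) within one
   Levenshtein edit; primer-trimmed reads split into an LCO-end and an
   HCO-end dataset per PCR replicate, which are dereplicated, with exact
   stage-by-stage accounting.
2. **OTU inference** (`oligocoi.otus`) — Kimura two-parameter distances
   d = −½·ln((1−2P−Q)·√(1−2Q)) (P transitions, Q transversions, pairwise
   deletion of ambiguous sites), neighbor-joining trees, and OTU delineation
   at the 10% COI divergence threshold: queries join the nearest reference
   OTU below threshold, the rest cluster by single linkage into new OTUs.
   Read counts are aggregated per OTU over the four datasets (2 ends x 2 PCR
   replicates) and averaged.
3. **Abundance correction** (`oligocoi.correction`) — for each sufficiently
   recurrent OTU, a multiplicative correction factor is fitted by exhaustive
   grid search ({0.1 … 1 step 0.05} ∪ {1 … 200 step 1}) minimizing the mean
   absolute difference, in percentage points, between specimen-based and
   read-based proportions across samples.
4. **IOBS index** (`oligocoi.iobs`) — IOBS = 10·S/T with S the number of
   taxa present and T the percentage of the dominant tubificid group (with
   or without hair setae); classes: >= 6 very good, [3, 6) good, [2, 3)
   medium, [1, 2) poor, < 1 bad. Computable from specimen counts, raw read
   means or corrected read means.
5. **Comparison** (`oligocoi.comparison`) — Sanger/NGS detection matrix,
   over/under-estimation skew ratios (flagging ratios > 2 in >= 2 samples),
   and Pearson/least-squares comparison of proportions per sample and pooled,
   before and after correction.
6. **Synthetic communities** (`oligocoi.synthetic`) — a generator for
   reference OTUs (>= 12% pairwise divergence), specimen communities,
   bias-skewed multinomial read counts and paired FASTQ with configurable
   error and quality models, so the whole pipeline is testable against known
   ground truth.

## Worked example

Simulate a four-sample study with strong per-OTU amplification bias, run the
full pipeline, fit correction factors and compare bases:

```python
import pandas as pd
from oligocoi import (SyntheticConfig, generate_dataset, FilterParams,
                      process_fastq, delineate_otus, end_reference,
                      count_reads_per_otu, community_table, optimize_factors,
                      apply_factors, comparison_report, iobs_report)
from oligocoi.otus import ENDS, REPLICATES

cfg = SyntheticConfig(n_otus=10, seq_length=400,
                      community_sizes=(40, 35, 50, 45), read_depth=2000,
                      per_base_error=0.0, quality_mean=40.0, quality_sd=0.0,
                      read_length=180, rng_seed=42)
ds = generate_dataset(cfg, "demo")

datasets, assignments = {}, {}
for (sid, rep), (r1, r2) in ds.fastq_paths.items():
    lco, hco, acc = process_fastq(r1, r2, FilterParams())
    datasets.setdefault(sid, {})[("LCO", rep)] = lco
    datasets[sid][("HCO", rep)] = hco
for end in ENDS:
    L = cfg.read_length - len(cfg.lco_primer if end == "LCO" else cfg.hco_primer)
    queries = {s for sid in datasets for rep in REPLICATES
               for s in datasets[sid][(end, rep)]}
    refs = {r.otu_id: end_reference(r.sequence, end, L) for r in ds.references}
    assignments[end] = delineate_otus({s: s for s in queries}, refs).as_mapping()

table = pd.concat([
    community_table(comm["otu_id"].value_counts().to_dict(),
                    count_reads_per_otu(datasets[sid], assignments)[0],
                    sample_id=sid)
    for sid, comm in ds.communities.items()], ignore_index=True)

factors = optimize_factors(table, min_samples=4)
pooled = (comparison_report(table, factors)
          .query("sample_id == 'pooled'").set_index("basis")["pearson_r"])
print(f"pooled r raw {pooled['raw']:.3f} corrected {pooled['corrected']:.3f}")

eco = {r.otu_id: r.eco_group for r in ds.references}
corrected = apply_factors(table, factors)
for basis in ("sanger", "ngs_uncorrected", "ngs_corrected"):
    r = next(x for x in iobs_report(corrected, eco, basis) if x.sample_id == "S1")
    print(f"S1 {basis}: S={r.n_taxa} T={r.pct_dominant_tubificids:.2f}% "
          f"IOBS={r.index} ({r.quality_class})")
```

prints

```
pooled r raw 0.249 corrected 0.741
S1 sanger: S=10 T=27.50% IOBS=3.64 (good)
S1 ngs_uncorrected: S=8 T=13.45% IOBS=5.95 (good)
S1 ngs_corrected: S=8 T=15.73% IOBS=5.09 (good)
```

The raw pooled Pearson correlation between specimen and read proportions is
weak (r = 0.249) because every OTU carries its own amplification efficiency
spanning ~4 decades; after fitting and jointly applying per-OTU correction
factors it rises to 0.741. The IOBS lines show the index inputs and verdict
for sample S1 on each abundance basis: S is the taxon count, T the dominant
tubificid percentage, and the corrected read basis moves the index toward
the specimen-based value. (Fitted factors recover *relative* amplification
bias: proportions are invariant to a global rescaling of efficiencies, so
factors are identifiable only up to a common constant.)

The same steps are available as a CLI:

```bash
oligocoi simulate --seed 42 --out-dir demo
oligocoi filter --r1 demo/S1_rep1_R1.fastq --r2 demo/S1_rep1_R2.fastq
oligocoi correct community_table.tsv --min-samples 4
oligocoi iobs community_table.tsv --eco-groups groups.tsv --basis sanger
```

## Documentation

`docs/methods.md` describes the models, their assumptions, parameter
choices and known limitations.
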