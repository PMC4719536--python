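# bacpool

Assembly support for pooled-BAC sequencing projects.

Large, repeat-rich plant genomes are often sequenced BAC by BAC, but
sequencing each of thousands of clones in its own library is costly.  A
practical compromise is to pool a few BACs whose physical-map positions
guarantee they do not overlap, sequence each pool deeply in one indexed
library, assemble the pool as a unit, and then *deconvolute* the pooled
assembly back to individual clones using their Sanger BAC-end sequences
(BES).  `bacpool` implements the computational side of that strategy:

- **Pool design** — partition clones into pools of non-overlapping BACs
  using the physical-map (FPC) contig layout, so that 384 clones yield
  96 pools of 4 on a single lane.
- **Read QC** — exact-match screening of read pairs against *E. coli* and
  cloning-vector references (pairs are removed atomically), followed by
  clonal-duplicate removal (a pair is a duplicate if it is byte-identical
  to an earlier pair, directly or as the mate-swapped reverse complement).
- **Coverage saturation** — subsample pairs with replacement on a 200x to
  3000x grid (100x steps), assemble each subsample, smooth assembly length
  with a from-scratch LOESS (tricube weights, local quadratic, span 0.75)
  and report the plateau coverage.
- **Deconvolution** — score every BES/contig alignment with
  `S = b − d_s`, where `b` is the bit score and `d_s` the distance of the
  alignment from the nearer contig end, and assign each BES to the contig
  with the highest score.  BES must be longer than 120 bp and shorter than
  a configurable ceiling; 120 bp vector-end proxies bypass the length
  filter.
- **Mate-pair QC and scaffolding links** — classify mapped mate pairs as
  RF (correct for outward-facing libraries), FR, or FF/RR; filter pairs
  for validation and scaffolding; bundle inter-contig links (default
  threshold 10 links) into gap estimates and an SSPACE-style tab file.
- **Simulator** — synthetic BAC pools with ground-truth labels (insert,
  *E. coli*, vector, clonal duplicate) for every read pair, used by the
  test suite and the acceptance script.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end checks; the rest of the
suite tests each module against worked examples, closed forms, and
brute-force oracles (e.g. LOESS against explicit normal equations, BES
scoring against exhaustive enumeration).

## Worked example

Simulate one pool of four 40 kb clones at 30x with default contamination
fractions, then run the QC stage:

```sh
bacpool simulate --pools 1 --clones-per-pool 4 --insert-length 40000 \
    --repeat-fraction 0.3 --coverage 30 --seed 42 --outdir sim
# -> wrote 1 pool(s) to sim   (reads, BES, truth table, contaminant refs)

bacpool qc --r1 sim/pool1_1.fq --r2 sim/pool1_2.fq \
    --ecoli ecoli.fa --vector vector.fa \
    --read-length 150 --n-bacs 4 --unit-length 40000 --out-prefix qc
# -> kept 15995/19184 pairs (vector 4.0%, ecoli 12.0%, clonal 0.6%)
```

(`ecoli.fa` / `vector.fa` are the two records of
`sim/pool1_contaminants.fa` split into separate files.)  The report
`qc_report.tsv` then reads:

```text
input_pairs  kept_pairs  vector_pct  ecoli_pct  clonal_pct  raw_coverage_x  filtered_coverage_x
19184        15995       4.0         12.0       0.63        36              30
```

The recovered percentages match the simulator's configured contamination
fractions (12 % *E. coli*, 4 % vector, 0.6 % clonal).  `bacpool run
--config pipeline.yaml` executes the full chain (QC → assembly →
deconvolution → mate-pair QC → links) and writes a deterministic
`manifest.json`; see `bacpool --help` for all subcommands.

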