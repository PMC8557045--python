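# herbminer

Frequent-itemset mining and prescription-rule analysis for herbal clinical
records. Given a corpus of prescription cases (an herb set plus optional
syndrome tags per case), the package computes:

- **Frequency profiles** — per-herb case counts/percentages and weighted
  property / taste / meridian distributions (attribute percentages share a
  single denominator: the total number of herb occurrences).
- **Frequent herb combinations** — exact-support Apriori mining (L1..Lk),
  with a brute-force oracle used to verify the miner in tests.
- **Basic and core prescriptions** — the "Top N groups" procedure: the
  highest-support itemset at the deepest frequent level is the motherboard;
  herbs contributed by the remaining top-ranked itemsets of that level are
  daughterboards; their union is the basic prescription, and its
  intersection with the top high-frequency herbs is the core prescription.
- **Herbal pairs** — 2-itemsets mined at high support on a
  syndrome-filtered sub-corpus.
- **Synthetic corpora** — a generator that plants template prescriptions
  (mixture of at most one template per case plus independent background
  herbs) with closed-form expected supports, for testing and calibration
  against published marginal counts.

`herbminer.reference` embeds the published aggregate tables of a 715-case
coronary-heart-disease prescription study (48 herb counts, attribute
counts, the seven five-herb combinations, 21 pair scores); the raw case
records are not publicly deposited, so these aggregates serve as
worked-example inputs and calibration targets.

## CLI

```sh
# full pipeline: load -> dedupe -> profiles -> Apriori -> basic/core prescription
herbminer mine --input cases.csv --attrs herb_attrs.csv \
    --min-support 0.3 --max-k 5 --top-m 6 --top-n all \
    --syndromes "qi deficiency;blood stasis" --out outdir/

# pair mining only, on the syndrome-filtered sub-corpus
herbminer pairs --input cases.csv --syndromes "qi deficiency;blood stasis" \
    --min-support 0.6 --out outdir/

# synthetic corpus from a YAML simulation config
herbminer simulate --config sim.yaml --seed 42 --out cases.csv --truth truth.json

# frequency + attribute tables only
herbminer profile --input cases.csv --attrs herb_attrs.csv --out outdir/
```

`mine` also accepts `--config pipeline.yaml` whose keys mirror
`PipelineConfig`; CLI flags override file values. Logging goes to stderr;
all machine outputs are files in `--out`. Re-running an identical
configuration produces byte-identical bundles.

Input schemas (UTF-8):

- prescriptions CSV: header `case_id,patient_id,herbs,syndromes`, with
  `herbs`/`syndromes` as `;`-separated lists (JSON equivalent: list of
  objects with the same keys and arrays);
- herb attributes CSV: `herb,property,tastes,meridians`;
- synonym map CSV: `raw,canonical`.

## Layout

| module | contents |
| --- | --- |
| `herbminer.corpus_io` | corpus/attribute/synonym parsing, standardization, first-prescription dedup, syndrome filtering |
| `herbminer.frequency_profile` | frequency tables, threshold filters, attribute profiles, display rounding |
| `herbminer.itemset_mining` | Apriori, brute-force oracle, support, rule confidence |
| `herbminer.prescription_extraction` | motherboard selection, Top-N-groups, core prescription, pair ranking |
| `herbminer.synthetic_data` | template-mixture generator, marginal calibration, planted truth, exact marginal realization |
| `herbminer.reference` | embedded published aggregates |
| `herbminer.cli` | `herbminer` command-line entry points and pipeline report bundle |
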