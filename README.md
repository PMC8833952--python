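# isomirdisp

Concurrent canonical / non-canonical miRNA-isoform (isomiR) analysis for
race-stratified small-RNA cohorts, as a tested, reusable pipeline:

- **isomiR calling** — ungapped placement of small-RNA reads on hairpin
  references, annotation of 5′/3′ end shifts, templated-ness, non-templated
  3′ additions (NTA) and single-nucleotide variants (A-to-I editing at
  catalogued sites, known DNA variants, unknown), terminal-SNV filtering,
  a deterministic parseable nomenclature, and the 4×4
  (shift class × variant class) category taxonomy.
- **Quantification** — count matrices, the ⌊RPM geometric mean⌋ > 1
  expression filter, TMM normalization factors computed from scratch
  (validated against edgeR), per-group expressed sets and intersections.
- **Four-group differential analysis** — Kruskal–Wallis across
  W(N)/W(T)/B-AA(N)/B-AA(T), Benjamini–Hochberg correction, six-trend
  classification of significant isoforms.
- **Quartile-stratified gene DE** — Q1-vs-Q3 split on one isomiR's
  expression, FPKM filtering, a negative-binomial exact test (binomial in
  the dispersion-0 limit), expression correlation, hypergeometric
  over-representation analysis.
- **Prognostic signature search** — the two-stage workflow: eligibility,
  correlation pruning swept over thresholds 0.60–0.80, univariate Cox
  (Efron ties, Newton–Raphson, BH-FDR < 0.05) → multivariate Cox (p < 0.05)
  → recursive feature elimination → risk score Σ expᵢ·βᵢ (univariate betas)
  → median split → Kaplan–Meier / log-rank / ROC-AUC, returning the
  AUC-best signature; cross-cohort application with a NOT_TESTABLE result
  when features are absent.
- **Synthetic data** — seed-deterministic generators with planted ground
  truth for every stage: reference bundles with registered seed-region
  editing sites, reads with known isoform events, four-group NB count
  matrices with known trends, and proportional-hazards survival cohorts.

## CLI

```sh
# generate synthetic inputs with planted truth
isomirdisp simulate reads    --seed 17 --n-hairpins 10 --depth 5000 --out sim/
isomirdisp simulate counts   --seed 1 --out counts/
isomirdisp simulate survival --seed 1 --n-patients 200 --out surv/

# call isomiRs against a reference bundle (hairpins.fa, matures.tsv, variants.tsv)
isomirdisp call --reference sim/ --reads sim/reads.fastq --out calls/

# expression filter, TMM factors, four-group trends
isomirdisp filter   --counts counts/counts.tsv --out filtered.tsv
isomirdisp quantify --counts counts/counts.tsv --out factors.tsv
isomirdisp trends   --counts filtered.tsv --samples samples.tsv --out trends.tsv

# quartile-stratified gene DE and the survival-signature search
isomirdisp stratify  --target '<isomiR name>' --isomir-counts ... --gene-counts ... --gene-fpkm ... --out de.tsv
isomirdisp signature --expr expr.tsv --samples samples.tsv --event os --group W --out sig.json
```

File formats are plain text throughout: FASTA for hairpins; TSV for mature
coordinates (0-based half-open on the hairpin), variant annotations
(1-based on the mature), sample sheets, count/FPKM matrices and results;
GFF3-dialect output for isomiR calls; JSON for signatures.

## Conventions

- Internal coordinates are 0-based half-open; genomic reporting is 1-based
  inclusive. U is normalized to T on ingest.
- isomiR offsets: `offset5 > 0` means the 5′ end is trimmed relative to the
  canonical mature; `offset3 > 0` means the 3′ terminus extends beyond the
  canonical end (templated extension and/or NTA).
- SNV positions are always on the canonical mature coordinate system, so
  "position 3" means seed position 3 for every isoform of a mature.
- Nomenclature: `<mature>|5p<o5>|3p<o3>|nta:<seq|->|snv:<pos><ref>><alt>:<class>[,…]|-`,
  injective and parseable back to the call.
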