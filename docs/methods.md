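# Methods

## Harmonization model

The unit of observation is a mutation *call*: one (subject, caller, site)
triple carrying tumor and normal allelic depths. Sites are identified by the
canonical key `chrom:pos:ref:alt` (VCF 1-based coordinates, `chr` prefixes
stripped by default), so the same variant reported by two callers collapses
onto one site. Identity is exact-representation identity: no left-alignment
or decomposition of INDELs is attempted, because no principled normalization
rule exists that all six dialects share; two representations of the same
indel therefore count as different sites, which slightly understates
consensus for indel-heavy data.

Per-dialect evidence extraction follows each caller's published FORMAT
conventions:

| dialect | tumor ref / alt depth | somatic status | variant types |
|---|---|---|---|
| mutect, mutect2, muse | `AD[0]` / `AD[alt index]` | somatic-only emitters | SNV (mutect, muse); +INDEL (mutect2) |
| somaticsniper | `BCOUNT` indexed by ref/alt base in A,C,G,T order | `SS` sample field (2 = somatic) | SNV |
| strelka | SNV: tier-1 of the ref-/alt-base `xU` field; INDEL: tier-1 `TAR`/`TIR` | somatic-only emitter | SNV, INDEL |
| varscan2 | `RD` / `AD` | `SS` sample or INFO field | SNV, INDEL |

Strelka's base-count fields are emitted as tier pairs by the released tool;
we use the tier-1 (high-confidence) component throughout, and extend the
same rule to its INDEL fields. Records whose depth fields are missing or
malformed are skipped, counted in a per-file parse report, and never abort a
run. Multi-allelic records are split into one call per ALT allele, indexing
`AD` accordingly. All records are ingested regardless of FILTER; the FILTER
string is retained so that filtering is an explicit, auditable downstream
step rather than a parsing side effect. When `somatic_only` is requested,
records whose dialect-reported inheritance is germline or LOH are dropped at
ingestion and counted.

Unknown somatic status is retained as `unknown` (and treated as passing a
somatic-only *filter*), on the view that a tumor-normal somatic caller's
output is somatic unless it says otherwise.

## Consensus statistics

For callers with site sets S_i in a scope, the co-occurrence matrix has
x_ii = |S_i| and x_ij = |S_i ∩ S_j|. The consensus score

CS = [ Σᵢ ( (1/x_ii) Σ_{j≠i} x_ij ) ] / (n(n−1))

uses the *total-sites* diagonal. The phrase "tool-specific calls" for the
diagonal could also be read as caller-*exclusive* calls; that normalisation
is unbounded above and undefined for callers without exclusive sites, so the
total-sites convention — under which CS lies in [0, 1], equals 1 exactly at
perfect consensus and 0 on pairwise-disjoint sets — is the default, and the
exclusive reading remains available via
`consensus_score_from_sets(..., diagonal="exclusive")`. Callers with zero
calls in scope are dropped before evaluation (their ratio is undefined) and
n counts the retained callers; fewer than two retained callers yield a
missing CS.

Cohort-scope units are (subject, site key) pairs — the same variant in two
subjects counts twice; subject scope uses bare site keys. Jaccard similarity
is J_ij = x_ij / (x_ii + x_jj − x_ij), missing when the union is empty.
Subject-by-subject co-occurrence is computed per caller; the dispersion of a
subject pair's shared count across callers is summarized by the coefficient
of variation with the sample (n−1) standard deviation, missing when the
pair co-occurs under no caller.

## Outlier criteria

Subjects are screened on four cohort-level criteria, each thresholded by
Tukey's fences (quartiles by linear interpolation between order statistics —
stated explicitly because fence placement depends on the quantile method;
k = 1.5 by default, configurable):

1. **hypermutated** — total distinct sites, high fence only;
2. **site-count imbalance** — sample CV of the subject's per-caller site
   counts, high fence;
3. **consensus imbalance** — sample CV of the subject's pairwise shared
   fractions x_ij/min(x_ii, x_jj), high fence;
4. **low consensus** — CS, low fence only (there is no such thing as
   suspiciously *high* consensus).

The CV statistics in (2) and (3) are this package's choice: they are
scale-free, so hypermutated subjects are not automatically imbalance
outliers. The underlying statistics are emitted alongside the flags so any
alternative can be recomputed from the report. Missing statistics exclude a
subject from that criterion only. Note that Tukey fences flag ~0.7% of draws
from any well-behaved unimodal distribution; in a homogeneous 50-subject
cohort an occasional background subject will therefore be flagged — that is
the method's stated false-positive rate, not a defect, and k can be raised
to trade sensitivity for specificity.

## Gene level

Gene (and exon) intervals come from user files: tab-delimited 1-based
inclusive, or BED (0-based half-open, converted on load; `.bed` suffix
decides). A site belongs to every gene whose interval contains its position
(INDELs located at their first reference base); no precedence rule is
applied. Per caller, the gene × subject matrix is 1 where the subject has
≥ 1 mutated site in the gene; f is the row mean over all catalogue
subjects, sd_f the sample SD of f across callers (a `union` column treats a
gene as mutated when any caller reports it). Distance to the nearest exon is
0 inside an exon and otherwise the gap to the nearest boundary with
adjacency counting as 1; chromosomes without exons give a missing value.

## Threshold sweeps

Counts are cumulative — sites with value ≥ cutoff, ties kept — per caller,
per (caller, subject), or per (subject, caller). Since a count axis can also
be read per-bin, a binned histogram is emitted alongside. Calls with a
missing value (VAF at zero total depth) are excluded from every count and
tallied separately rather than treated as zero. Default grids: VAF 0–0.5 in
steps of 0.01; depths 0–50 in steps of 1.

## Filtering

A (subject, site) survives when it has ≥ `min_callers` supporting callers
and every active per-call criterion (tumor alt depth, tumor VAF, normal VAF,
somatic status) is met by **at least one** supporting call; a strict mode
requires **all** calls to pass. The permissive default reflects that
disagreement about depths between callers should not veto a site that at
least one caller observed with adequate evidence. Criteria are applied in a
fixed order (caller support → depth → VAF → somatic → catalogue → exon
distance → whitelists) so attrition reports are deterministic and
comparable. Known-site matching reads the four standard MAF columns
(Chromosome, Start_Position, Reference_Allele, Tumor_Seq_Allele2) from a
local table, gzip accepted, in exact (`chrom:pos:ref:alt`) or position-only
mode. Filtering is idempotent and monotone in each threshold; both
properties are tested.

## Synthetic cohorts

The generator emulates a tumor-normal cohort analysed by several callers:

- per subject, T ~ Poisson(λ) true somatic sites at distinct uniform
  positions on a toy contig (default length 10⁷ — roughly a gene-dense
  chromosome arm, large enough that position collisions are negligible);
  λ = 100 by default, a typical exome-scale somatic burden;
- each caller detects each true site independently with sensitivity p_c
  (default 0.8, the ballpark of published somatic-caller sensitivities) and
  adds Poisson(φ_c) exclusive false sites (default 10 per subject);
- tumor depth is negative-binomial (mean 80, shape 8) plus a floor of 10 —
  exome-like coverage with realistic overdispersion; the alt count is
  binomial given a site VAF drawn from Beta(2, 3) for true sites (mean 0.4,
  the clonal-heterozygous region) and Beta(1.2, 12) for false positives
  (mean ≈ 0.09), mimicking the low-VAF excess of permissive callers; a
  called site always has ≥ 1 supporting read;
- plantable outlier subjects: hypermutated (λ × 10), weak caller (the first
  caller's p drops to 0.2 for that subject), discordant (φ × 10 for every
  caller);
- optional `couple_detections` shares one detection draw per true site
  across callers, giving identical per-caller detections when sensitivities
  are equal — the degenerate case in which sd_f must be exactly 0.

Each subject consumes its own deterministically derived random substream
(`default_rng([seed, subject_index])`), so cohorts are byte-reproducible and
a subject's data do not depend on cohort size. SNV-only dialects never
receive INDEL records (the writer rejects them); the default cohort is
SNV-only (`indel_fraction = 0`) so that all six dialects see identical
truth, and an indel fraction can be switched on when mixed-type behaviour is
wanted.

What the generator does **not** emulate: sequence context and mutational
signatures, caller-correlated errors (real callers miss the same
hard-to-align regions together), mapping artefacts clustered near indels,
tumor purity/subclonality structure, and between-subject heterogeneity of
mutation burden beyond the explicit outlier plan. Passing tests on these
cohorts therefore validate the *bookkeeping and statistics* — parsing,
integration, scores, fences, filters — not the biological plausibility of
any particular caller's error profile.

## Numerical and reporting choices

Quantiles use linear interpolation; CVs and sd_f use the sample (n−1)
standard deviation; 0/0 ratios (VAF at zero depth, CV at zero mean, Jaccard
of empty unions) are missing values, never 0. Reports are UTF-8 TSV with
`NA` for missing and floats at 6 significant digits, making byte-identical
reruns achievable; the `--threads` flag is accepted for interface
compatibility and never influences output content. Every CLI run writes a
JSON manifest with parameters, input SHA-256 hashes and the output file
list.

## Known limitations

- Exact-representation site identity understates consensus across callers
  that normalize indels differently.
- The bundled dialect writers emit minimal, synthetic VCFs; real caller
  outputs carry many more annotations, which the parsers ignore rather than
  validate.
- Tukey-fence outlier detection is descriptive, not model-based, and applies
  no multiple-testing control; on tightly concentrated cohorts it will flag
  a small fraction of unremarkable subjects by construction.
- Known-catalogue matching is a local-file membership test; it does not
  query any remote mutation database.
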