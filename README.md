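# multicall

Integrative analysis of somatic mutations detected by multiple tumor–normal
variant-calling pipelines.

Somatic mutation callers disagree: run Mutect2, MuSE, SomaticSniper, Strelka
and VarScan2 on the same tumor–normal pair and you get five different site
lists, each encoding the supporting read evidence in its own VCF dialect
(`AD` pairs, `BCOUNT` quadruples, `AU/CU/GU/TU` tier pairs, `RD`+`AD`
scalars). `multicall` is for analysts who integrate such multi-caller
outputs across a cohort: it harmonizes the per-caller VCFs into one mutation
catalogue with canonical `chrom:pos:ref:alt` site keys, quantifies how much
the callers agree, flags subjects that behave abnormally, and screens sites
with composable filters — including matching against a local known-mutation
catalogue (e.g. a MAF export).

## The statistics at the core

Let **x** be the caller-by-caller site co-occurrence matrix in some scope
(cohort or single subject): `x_ii` is the number of distinct sites reported
by caller *i*, and `x_ij` (i ≠ j) the number reported by both *i* and *j*.
From **x** the package computes:

- the **consensus score**

  CS = [ Σᵢ ( (1/x_ii) Σ_{j≠i} x_ij ) ] / P(n, 2),    P(n, 2) = n(n−1),

  a per-subject scalar in [0, 1]: 1 when all callers report identical site
  sets, 0 when they are pairwise disjoint. Callers with no calls in scope are
  dropped before evaluation.
- the **Jaccard similarity** J_ij = x_ij / (x_ii + x_jj − x_ij) between
  callers, and subject-by-subject co-occurrence with the coefficient of
  variation of each pair's shared count across callers;
- **outlier subjects** under Tukey's fences (Q1 − k·IQR, Q3 + k·IQR,
  k = 1.5) on four criteria: total site count (hypermutation, high fence),
  CV of per-caller site counts (site-count imbalance, high fence), CV of
  pairwise shared fractions x_ij/min(x_ii, x_jj) (consensus imbalance, high
  fence), and CS (low fence);
- per caller, the binary **gene × subject mutation matrix**, the gene
  mutation frequency *f* (fraction of subjects with ≥ 1 mutation in the
  gene) and its cross-caller dispersion sd_f;
- **threshold sweeps**: the number of surviving sites as a minimum tumor
  VAF / alt-read / depth cutoff rises, per caller and per subject.

A bundled synthetic-cohort generator writes dialect-faithful VCFs with known
ground truth (per-caller sensitivity, false-positive rate, depth and VAF
models, plantable outlier subjects), so the entire pipeline can be exercised
and validated without access to protected data.

## Worked example

Simulate a six-subject cohort analysed by all six callers, planting one
hypermutated subject, then run the site-level analysis:

```sh
multicall simulate --n-subjects 6 --mean-sites 40 --seed 42 \
    --outlier 2:hypermutated --out demo/cohort
multicall site-analysis --config demo/cohort/config.tsv --out demo/reports
```

`demo/reports/overall_consensus.tsv` — per-caller totals and the fraction of
each caller's sites confirmed by at least one other caller:

```
caller	total	exclusive_fraction	shared_fraction
muse	530	0.132075	0.867925
mutect	506	0.0988142	0.901186
mutect2	511	0.107632	0.892368
somaticsniper	516	0.125969	0.874031
strelka	515	0.106796	0.893204
varscan2	522	0.124521	0.875479
```

At the defaults (80% per-caller sensitivity, ~10 false positives per caller
and subject) every caller finds ~510 of the cohort's sites and ~10–13% of
its calls are caller-exclusive — false positives plus sites the other
callers missed.

`demo/reports/subject_consensus.tsv` — per subject, the union site count,
per-caller counts, the fraction of sites with ≥ 2-caller support and the CS:

```
subject	n_sites	n_muse	n_mutect	n_mutect2	n_somaticsniper	n_strelka	n_varscan2	frac_k_ge_2	CS
S00	98	46	44	43	45	47	49	0.459184	0.661174
S01	107	52	38	43	47	52	46	0.429907	0.610908
S02	437	321	306	309	305	306	311	0.842105	0.780339
S03	92	37	38	40	42	32	38	0.369565	0.618108
S04	100	44	46	46	42	47	42	0.45	0.621024
S05	91	30	34	30	35	31	36	0.296703	0.561864
```

S02 carries ~4× the sites of its peers (the planted hypermutated subject —
its fixed false-positive load is diluted, so its consensus is *higher*), and
`outlier_subjects.tsv` flags it on the hypermutation criterion and nothing
else:

```
subject	n_sites	imbalance_stat	consensus_imbalance_stat	CS	hypermutated	site_count_imbalance	consensus_imbalance	low_CS
S02	437	0.0193398	0.0140407	0.780339	YES	NO	NO	NO
```

The same catalogue can then be screened, e.g. keeping sites supported by at
least two callers with tumor VAF ≥ 0.1:

```sh
multicall filter --config demo/cohort/config.tsv --min-callers 2 \
    --min-tumor-vaf 0.1 --out demo/filtered
```

which writes the surviving catalogue, a per-criterion attrition report and a
merged VCF whose INFO fields carry the supporting callers per site.

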