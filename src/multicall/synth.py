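"""Synthetic multi-caller cohorts with ground truth.

The generator emulates the structure of a tumor-normal cohort analysed by
several somatic callers: each subject carries a Poisson number of true
somatic sites at distinct positions on a toy contig; each caller detects a
true site independently with its sensitivity p_c and adds its own Poisson
number of exclusive false-positive sites. Tumor depths are negative-binomial,
alt counts binomial given a Beta-distributed VAF (false positives draw from a
low-VAF Beta, mimicking the low-VAF excess of permissive callers). Every
(subject, caller) list is written as a VCF in that caller's dialect, so the
whole pipeline is exercised end-to-end from files.

The dialect writers are the exact inverses of the harmonization parsers and
back the round-trip tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import CALLERS, SNV_ONLY_CALLERS, MutationCall, classify_variant

_BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Outlier kinds plantable into a cohort.
OUTLIER_KINDS = ("hypermutated", "weak_caller", "discordant")


@dataclass
class CohortSpec:
    """Generative parameters of one synthetic cohort.

    ``sensitivity`` and ``fp_rate`` accept a scalar (shared by all callers)
    or a per-caller mapping. ``outliers`` lists (subject index, kind) pairs:
    ``hypermutated`` multiplies the subject's site mean by 10, ``weak_caller``
    drops the first caller's sensitivity to 0.2 for that subject, and
    ``discordant`` multiplies every caller's false-positive mean by 10.
    ``couple_detections`` makes all callers share one detection draw per true
    site (callers then agree exactly when sensitivities are equal).
    """

    n_subjects: int = 20
    callers: Sequence[str] = CALLERS
    mean_sites_per_subject: float = 100.0
    sensitivity: Union[float, dict] = 0.8
    fp_rate: Union[float, dict] = 10.0
    mean_depth: float = 80.0
    depth_dispersion: float = 8.0  # negative-binomial shape; larger = tighter
    vaf_alpha: float = 2.0
    vaf_beta: float = 3.0
    fp_vaf_alpha: float = 1.2
    fp_vaf_beta: float = 12.0
    indel_fraction: float = 0.0
    contig: str = "1"
    contig_length: int = 10_000_000
    outliers: list[tuple[int, str]] = field(default_factory=list)
    couple_detections: bool = False
    seed: int = 0

    def caller_sensitivity(self, caller: str) -> float:
        if isinstance(self.sensitivity, dict):
            return float(self.sensitivity[caller])
        return float(self.sensitivity)

    def caller_fp_rate(self, caller: str) -> float:
        if isinstance(self.fp_rate, dict):
            return float(self.fp_rate[caller])
        return float(self.fp_rate)

    def validate(self) -> None:
        for c in self.callers:
            if c not in CALLERS:
                raise ValueError(f"unknown caller {c!r}")
            if not 0 <= self.caller_sensitivity(c) <= 1:
                raise ValueError("sensitivities must lie in [0, 1]")
            if self.caller_fp_rate(c) < 0:
                raise ValueError("false-positive rates must be >= 0")
        if self.mean_sites_per_subject <= 0 or self.mean_depth <= 0:
            raise ValueError("means must be positive")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must lie in [0, 1]")
        for idx, kind in self.outliers:
            if not 0 <= idx < self.n_subjects:
                raise ValueError(f"outlier subject index {idx} out of range")
            if kind not in OUTLIER_KINDS:
                raise ValueError(f"unknown outlier kind {kind!r}")


@dataclass
class TruthManifest:
    """Planted ground truth of a generated cohort."""

    true_sites: dict[str, list[str]]  # subject -> true site keys
    detected: dict[tuple[str, str], list[str]]  # (subject, caller) -> keys
    false_sites: dict[tuple[str, str], list[str]]
    outlier_labels: dict[str, str]  # subject -> kind

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subj, keys in self.true_sites.items():
            for key in keys:
                rows.append({"subject": subj, "site": key, "status": "true",
                             "caller": "*"})
        for (subj, caller), keys in self.detected.items():
            for key in keys:
                rows.append({"subject": subj, "site": key, "status": "detected",
                             "caller": caller})
        for (subj, caller), keys in self.false_sites.items():
            for key in keys:
                rows.append({"subject": subj, "site": key, "status": "false",
                             "caller": caller})
        return pd.DataFrame(rows, columns=["subject", "site", "status", "caller"])


def _draw_site(rng: np.random.Generator, spec: CohortSpec,
               used: set[int], indel: bool) -> tuple[int, str, str]:
    for _ in range(10000):
        pos = int(rng.integers(1, spec.contig_length))
        if pos not in used:
            used.add(pos)
            break
    else:
        raise RuntimeError(
            "position space exhausted; increase contig_length")
    ref = _BASES[rng.integers(0, 4)]
    if not indel:
        alt = _BASES[(int(rng.integers(1, 4)) + _BASE_INDEX[ref]) % 4]
    elif rng.random() < 0.5:  # insertion
        alt = ref + "".join(_BASES[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
    else:  # deletion
        ref = ref + "".join(_BASES[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
        alt = ref[0]
    return pos, ref, alt


def _draw_depths(rng: np.random.Generator, spec: CohortSpec,
                 vaf: float) -> tuple[int, int, int, int]:
    shape = spec.depth_dispersion
    depth = int(rng.negative_binomial(shape, shape / (shape + spec.mean_depth))) + 10
    t_alt = int(rng.binomial(depth, vaf))
    if t_alt == 0:
        t_alt = 1  # a called site has at least one supporting read
    n_depth = int(rng.negative_binomial(shape, shape / (shape + spec.mean_depth))) + 10
    return depth - t_alt if depth > t_alt else 0, t_alt, n_depth, 0


def _make_call(rng: np.random.Generator, spec: CohortSpec, subject: str,
               caller: str, pos: int, ref: str, alt: str,
               low_vaf: bool) -> MutationCall:
    a, b = ((spec.fp_vaf_alpha, spec.fp_vaf_beta) if low_vaf
            else (spec.vaf_alpha, spec.vaf_beta))
    vaf = float(rng.beta(a, b))
    t_ref, t_alt, n_ref, n_alt = _draw_depths(rng, spec, vaf)
    return MutationCall(
        subject_id=subject, caller_id=caller, chrom=spec.contig,
        pos=pos, ref=ref, alt=alt, vtype=classify_variant(ref, alt),
        inheritance="somatic", tumor_ref_depth=t_ref, tumor_alt_depth=t_alt,
        normal_ref_depth=n_ref, normal_alt_depth=n_alt)


def simulate_calls(spec: CohortSpec) -> tuple[dict[tuple[str, str], list[MutationCall]],
                                              TruthManifest]:
    """Draw the cohort in memory: (subject, caller) -> harmonized calls.

    Each subject consumes an independent, deterministically derived random
    substream, so a subject's data do not depend on cohort size.
    """
    spec.validate()
    callers = list(spec.callers)
    outlier_map = {idx: kind for idx, kind in spec.outliers}
    width = max(2, len(str(spec.n_subjects)))
    calls: dict[tuple[str, str], list[MutationCall]] = {}
    truth = TruthManifest({}, {}, {}, {})

    for s_idx in range(spec.n_subjects):
        subject = f"S{s_idx:0{width}d}"
        rng = np.random.default_rng([spec.seed, s_idx])
        kind = outlier_map.get(s_idx)
        if kind:
            truth.outlier_labels[subject] = kind
        lam = spec.mean_sites_per_subject * (10 if kind == "hypermutated" else 1)
        n_true = int(rng.poisson(lam))
        used: set[int] = set()
        true_sites = []
        for _ in range(n_true):
            indel = bool(rng.random() < spec.indel_fraction)
            true_sites.append(_draw_site(rng, spec, used, indel))
        truth.true_sites[subject] = [
            f"{spec.contig}:{p}:{r}:{a}" for p, r, a in true_sites]

        shared_draws = rng.random(n_true) if spec.couple_detections else None

        for c_idx, caller in enumerate(callers):
            p = spec.caller_sensitivity(caller)
            if kind == "weak_caller" and c_idx == 0:
                p = 0.2
            snv_only = caller in SNV_ONLY_CALLERS
            if spec.couple_detections:
                draws = shared_draws
            else:
                draws = rng.random(n_true)
            detected, caller_calls = [], []
            for i, (pos, ref, alt) in enumerate(true_sites):
                if snv_only and (len(ref) > 1 or len(alt) > 1):
                    continue
                if n_true and draws[i] < p:
                    caller_calls.append(_make_call(
                        rng, spec, subject, caller, pos, ref, alt, low_vaf=False))
                    detected.append(f"{spec.contig}:{pos}:{ref}:{alt}")
            phi = spec.caller_fp_rate(caller) * (10 if kind == "discordant" else 1)
            n_fp = int(rng.poisson(phi))
            false_keys = []
            for _ in range(n_fp):
                pos, ref, alt = _draw_site(rng, spec, used, indel=False)
                caller_calls.append(_make_call(
                    rng, spec, subject, caller, pos, ref, alt, low_vaf=True))
                false_keys.append(f"{spec.contig}:{pos}:{ref}:{alt}")
            calls[(subject, caller)] = caller_calls
            truth.detected[(subject, caller)] = detected
            truth.false_sites[(subject, caller)] = false_keys
    return calls, truth


def simulate_catalog(spec: CohortSpec):
    """In-memory shortcut: simulate a cohort straight into a catalogue.

    Equivalent to generating VCFs and harmonizing them, minus the file
    round trip; used where only the integrated calls matter.
    """
    from .core import MutationCatalog

    calls, truth = simulate_calls(spec)
    catalog = MutationCatalog()
    for (subject, caller) in sorted(calls):
        if subject not in catalog.subjects:
            catalog.subjects.append(subject)
        if caller not in catalog.callers:
            catalog.callers.append(caller)
        for call in calls[(subject, caller)]:
            catalog.add(call)
    return catalog, truth


# ---------------------------------------------------------------------------
# Dialect VCF writers (inverse of the harmonization parsers)

_HEADERS = {
    "ad": '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    "bcount": '##FORMAT=<ID=BCOUNT,Number=4,Type=Integer,Description="Reads per base: A,C,G,T">',
    "ss_fmt": '##FORMAT=<ID=SS,Number=1,Type=Integer,Description="Somatic status: 0=unknown,1=germline,2=somatic,3=LOH">',
    "tier": '##FORMAT=<ID={id},Number=2,Type=Integer,Description="{desc} tier1,tier2">',
    "rd": '##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Reference-supporting read depth">',
    "ad1": '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Variant-supporting read depth">',
    "ss_info": '##INFO=<ID=SS,Number=1,Type=Integer,Description="Somatic status: 0=unknown,1=germline,2=somatic,3=LOH">',
    "gt": '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
}

_SS_TO_CODE = {"unknown": 0, "germline": 1, "somatic": 2, "LOH": 3}


def _dialect_header(dialect: str, contigs: Sequence[str],
                    tumor: str, normal: str) -> str:
    lines = ["##fileformat=VCFv4.2", f"##source=synthetic-{dialect}",
             _HEADERS["gt"]]
    if dialect in ("mutect", "mutect2", "muse"):
        lines.append(_HEADERS["ad"])
    elif dialect == "somaticsniper":
        lines += [_HEADERS["bcount"], _HEADERS["ss_fmt"]]
    elif dialect == "strelka":
        for base in _BASES:
            lines.append(_HEADERS["tier"].format(id=f"{base}U", desc=f"{base} counts"))
        lines.append(_HEADERS["tier"].format(id="TAR", desc="Ref-allele counts"))
        lines.append(_HEADERS["tier"].format(id="TIR", desc="Indel-allele counts"))
    elif dialect == "varscan2":
        lines += [_HEADERS["rd"], _HEADERS["ad1"], _HEADERS["ss_info"]]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for contig in contigs:
        lines.append(f"##contig=<ID={contig}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{normal}\t{tumor}")
    return "\n".join(lines) + "\n"


def _sample_fields(dialect: str, call: MutationCall,
                   tumor: bool) -> tuple[str, str]:
    """(FORMAT, sample-column) strings for one call and one sample."""
    if tumor:
        ref_d, alt_d = call.tumor_ref_depth, call.tumor_alt_depth
        gt = "0/1"
    else:
        ref_d = call.normal_ref_depth if call.normal_ref_depth is not None else 0
        alt_d = call.normal_alt_depth if call.normal_alt_depth is not None else 0
        gt = "0/0"
    if dialect in ("mutect", "mutect2", "muse"):
        return "GT:AD", f"{gt}:{ref_d},{alt_d}"
    if dialect == "somaticsniper":
        bcount = [0, 0, 0, 0]
        bcount[_BASE_INDEX[call.ref]] = ref_d
        bcount[_BASE_INDEX[call.alt]] = alt_d
        ss = _SS_TO_CODE.get(call.inheritance, 0) if tumor else 0
        return "GT:BCOUNT:SS", f"{gt}:{','.join(map(str, bcount))}:{ss}"
    if dialect == "strelka":
        if call.vtype == "SNV":
            fmt = ":".join(f"{b}U" for b in _BASES)
            counts = {b: [0, 0] for b in _BASES}
            counts[call.ref][0] = ref_d
            counts[call.alt][0] = alt_d
            # tier-2 mirrors tier-1 in synthetic output
            counts[call.ref][1] = ref_d
            counts[call.alt][1] = alt_d
            return "GT:" + fmt, gt + ":" + ":".join(
                f"{counts[b][0]},{counts[b][1]}" for b in _BASES)
        return "GT:TAR:TIR", f"{gt}:{ref_d},{ref_d}:{alt_d},{alt_d}"
    if dialect == "varscan2":
        return "GT:RD:AD", f"{gt}:{ref_d}:{alt_d}"
    raise ValueError(f"unknown dialect {dialect!r}")


def write_vcf_dialect(calls: Sequence[MutationCall], dialect: str, path,
                      tumor_sample: str = "TUMOR",
                      normal_sample: str = "NORMAL") -> None:
    """Write calls as a VCF in the given caller's dialect.

    SNV-only dialects (mutect, muse, somaticsniper) reject non-SNV calls.
    Records are sorted by position for validity of downstream indexing.
    """
    if dialect in SNV_ONLY_CALLERS:
        bad = [c for c in calls if c.vtype != "SNV"]
        if bad:
            raise ValueError(
                f"{dialect} emits SNVs only; got {bad[0].vtype} at "
                f"{bad[0].chrom}:{bad[0].pos}")
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    contigs: list[str] = []
    for c in ordered:
        if c.chrom not in contigs:
            contigs.append(c.chrom)
    with open(path, "w") as fh:
        fh.write(_dialect_header(dialect, contigs, tumor_sample, normal_sample))
        for call in ordered:
            fmt, tumor_col = _sample_fields(dialect, call, tumor=True)
            _, normal_col = _sample_fields(dialect, call, tumor=False)
            info = "."
            if dialect == "varscan2":
                info = f"SS={_SS_TO_CODE.get(call.inheritance, 0)}"
            fh.write(f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}"
                     f"\t.\t{call.filter_field}\t{info}\t{fmt}"
                     f"\t{normal_col}\t{tumor_col}\n")


def generate_cohort(spec: CohortSpec, out_dir) -> tuple[str, TruthManifest]:
    """Write a full synthetic cohort: per-(subject, caller) VCFs, the run
    config and the truth manifest. Returns (config path, manifest).

    Byte-identical across reruns with the same spec and seed.
    """
    os.makedirs(out_dir, exist_ok=True)
    calls, truth = simulate_calls(spec)
    config_rows = []
    for (subject, caller), caller_calls in calls.items():
        vcf_path = os.path.join(out_dir, f"{subject}.{caller}.vcf")
        write_vcf_dialect(caller_calls, caller, vcf_path)
        config_rows.append((subject, caller, f"{subject}.{caller}.vcf",
                            "TUMOR", "NORMAL"))
    config_path = os.path.join(out_dir, "config.tsv")
    with open(config_path, "w") as fh:
        fh.write("subject_id\tcaller\tpath\ttumor_sample\tnormal_sample\n")
        for row in sorted(config_rows):
            fh.write("\t".join(row) + "\n")
    truth.to_frame().to_csv(os.path.join(out_dir, "truth_manifest.tsv"),
                            sep="\t", index=False)
    return config_path, truth
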