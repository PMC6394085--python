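"""Read run configurations and caller VCF outputs into one catalogue.

Somatic callers encode the same evidence differently: allelic depth lives in
``AD`` pairs (mutect, mutect2, muse), in a ``BCOUNT`` quadruple ordered
A,C,G,T (somaticsniper), in per-base tier pairs ``AU/CU/GU/TU`` for SNVs and
``TAR/TIR`` for INDELs (strelka), or in separate ``RD``/``AD`` scalars
(varscan2). This module maps each dialect onto :class:`~multicall.core.MutationCall`
records with a shared site key, which is the precondition for every
cross-caller comparison downstream.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    GENERIC_TSV,
    VALID_CALLERS,
    ConfigError,
    MutationCall,
    MutationCatalog,
    classify_variant,
    compute_vaf,
)

log = logging.getLogger(__name__)

CONFIG_HEADER = ["subject_id", "caller", "path", "tumor_sample", "normal_sample"]

#: Varscan2/SomaticSniper somatic-status codes (SS field).
_SS_CODES = {0: "unknown", 1: "germline", 2: "somatic", 3: "LOH", 5: "unknown"}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class ConfigEntry:
    subject_id: str
    caller_id: str
    path: str
    tumor_sample: str
    normal_sample: str


@dataclass
class RunConfig:
    entries: list[ConfigEntry]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def parse_config(path) -> RunConfig:
    """Parse the tab-delimited subject x caller -> VCF mapping.

    The header must be exactly ``subject_id  caller  path  tumor_sample
    normal_sample``. Relative VCF paths are resolved against the config
    file's directory.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CONFIG_HEADER:
            raise ConfigError(
                f"bad config header {header!r}; expected {CONFIG_HEADER!r}")
        base = os.path.dirname(os.path.abspath(path))
        entries: list[ConfigEntry] = []
        seen: set[tuple[str, str]] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ConfigError(f"line {lineno}: expected 5 fields, got {len(fields)}")
            subject, caller, vcf_path, tumor, normal = fields
            if caller not in VALID_CALLERS:
                raise ConfigError(f"line {lineno}: unknown caller {caller!r}")
            if (subject, caller) in seen:
                raise ConfigError(f"line {lineno}: duplicate entry ({subject}, {caller})")
            seen.add((subject, caller))
            if not os.path.isabs(vcf_path):
                vcf_path = os.path.join(base, vcf_path)
            if not os.path.exists(vcf_path):
                raise IOError(f"line {lineno}: file not found: {vcf_path}")
            entries.append(ConfigEntry(subject, caller, vcf_path, tumor, normal))
    if not entries:
        log.warning("config %s contains no entries", path)
    return RunConfig(entries)


class RecordParseError(ValueError):
    """A single VCF data line could not be harmonized; the line is skipped."""


def _fmt_row(variant, field: str, sample_idx: int) -> np.ndarray:
    arr = variant.format(field)
    if arr is None:
        raise RecordParseError(f"missing FORMAT field {field}")
    return np.atleast_2d(arr)[sample_idx]


def extract_allelic_depth(variant, dialect: str, sample_idx: int,
                          ref: str, alt: str) -> tuple[int, int]:
    """Reference/alternate read counts for one sample under one dialect.

    ``ref``/``alt`` are the alleles of the (possibly split) call; for
    multi-allelic AD records the ALT index within the record is used.
    """
    if dialect in ("mutect", "mutect2", "muse"):
        ad = _fmt_row(variant, "AD", sample_idx)
        alts = list(variant.ALT)
        try:
            alt_i = alts.index(alt) + 1
        except ValueError:
            raise RecordParseError(f"alt {alt} not in record ALTs {alts}")
        if len(ad) <= alt_i:
            raise RecordParseError(f"AD has {len(ad)} values, need index {alt_i}")
        return int(ad[0]), int(ad[alt_i])
    if dialect == "somaticsniper":
        bcount = _fmt_row(variant, "BCOUNT", sample_idx)
        if len(bcount) < 4:
            raise RecordParseError("BCOUNT must hold 4 values (A,C,G,T)")
        try:
            return int(bcount[_BASE_INDEX[ref]]), int(bcount[_BASE_INDEX[alt]])
        except KeyError as exc:
            raise RecordParseError(f"non-SNV allele for BCOUNT: {exc}")
    if dialect == "strelka":
        if len(ref) == 1 and len(alt) == 1 and ref in _BASE_INDEX and alt in _BASE_INDEX:
            ref_tier = _fmt_row(variant, f"{ref}U", sample_idx)
            alt_tier = _fmt_row(variant, f"{alt}U", sample_idx)
            return int(ref_tier[0]), int(alt_tier[0])
        # INDELs carry tier pairs in TAR (ref-supporting) / TIR (indel-supporting)
        tar = _fmt_row(variant, "TAR", sample_idx)
        tir = _fmt_row(variant, "TIR", sample_idx)
        return int(tar[0]), int(tir[0])
    if dialect == "varscan2":
        rd = _fmt_row(variant, "RD", sample_idx)
        ad = _fmt_row(variant, "AD", sample_idx)
        return int(np.atleast_1d(rd)[0]), int(np.atleast_1d(ad)[0])
    raise RecordParseError(f"unknown dialect {dialect!r}")


def _somatic_status(variant, dialect: str, tumor_idx: int) -> str:
    """Inheritance class of a record; non-reporting callers are somatic-only."""
    if dialect == "somaticsniper":
        try:
            ss = int(np.atleast_1d(_fmt_row(variant, "SS", tumor_idx))[0])
        except (RecordParseError, KeyError):
            return "unknown"
        return _SS_CODES.get(ss, "unknown")
    if dialect == "varscan2":
        try:
            arr = variant.format("SS")
        except KeyError:
            arr = None
        if arr is not None:
            raw = np.atleast_2d(arr)[tumor_idx]
            raw = raw[0] if np.ndim(raw) else raw
            try:
                return _SS_CODES.get(int(raw), "unknown")
            except (TypeError, ValueError):
                return "unknown"
        info_ss = variant.INFO.get("SS")
        if info_ss is not None:
            try:
                return _SS_CODES.get(int(info_ss), "unknown")
            except (TypeError, ValueError):
                return "unknown"
        return "unknown"
    return "somatic"


def _sample_indices(samples: list[str], entry: ConfigEntry) -> tuple[int, Optional[int]]:
    tumor, normal = entry.tumor_sample, entry.normal_sample
    if tumor not in samples and set(samples) == {"TUMOR", "NORMAL"}:
        tumor, normal = "TUMOR", "NORMAL"
    if tumor not in samples:
        raise RecordParseError(
            f"tumor sample {tumor!r} not among VCF samples {samples}")
    normal_idx = samples.index(normal) if normal in samples else None
    return samples.index(tumor), normal_idx


def _parse_vcf(entry: ConfigEntry, strip_chr: bool) -> tuple[list[MutationCall], dict]:
    calls: list[MutationCall] = []
    stats = {"lines_read": 0, "skipped_malformed": 0}
    vcf = VCF(entry.path)
    try:
        tumor_idx, normal_idx = _sample_indices(vcf.samples, entry)
        for variant in vcf:
            stats["lines_read"] += 1
            chrom = variant.CHROM
            if strip_chr and chrom.startswith("chr"):
                chrom = chrom[3:]
            ref = variant.REF
            filt = variant.FILTER or "PASS"
            for alt in variant.ALT:
                try:
                    t_ref, t_alt = extract_allelic_depth(
                        variant, entry.caller_id, tumor_idx, ref, alt)
                    n_ref = n_alt = None
                    if normal_idx is not None:
                        try:
                            n_ref, n_alt = extract_allelic_depth(
                                variant, entry.caller_id, normal_idx, ref, alt)
                        except RecordParseError:
                            n_ref = n_alt = None
                    calls.append(MutationCall(
                        subject_id=entry.subject_id,
                        caller_id=entry.caller_id,
                        chrom=chrom, pos=variant.POS, ref=ref, alt=alt,
                        vtype=classify_variant(ref, alt),
                        inheritance=_somatic_status(variant, entry.caller_id, tumor_idx),
                        tumor_ref_depth=max(t_ref, 0),
                        tumor_alt_depth=max(t_alt, 0),
                        normal_ref_depth=n_ref, normal_alt_depth=n_alt,
                        filter_field=filt,
                    ))
                except (RecordParseError, ValueError) as exc:
                    stats["skipped_malformed"] += 1
                    log.debug("%s:%s skipped: %s", entry.path, variant.POS, exc)
    finally:
        vcf.close()
    return calls, stats


_GENERIC_COLS = ["subject", "caller", "chrom", "pos", "ref", "alt",
                 "t_ref", "t_alt", "n_ref", "n_alt"]


def _parse_generic_tsv(entry: ConfigEntry, strip_chr: bool) -> tuple[list[MutationCall], dict]:
    opener = gzip.open if str(entry.path).endswith(".gz") else open
    with opener(entry.path, "rt") as fh:
        frame = pd.read_csv(fh, sep="\t")
    missing = [c for c in _GENERIC_COLS if c not in frame.columns]
    if missing:
        raise IOError(f"{entry.path}: generic table lacks columns {missing}")
    calls: list[MutationCall] = []
    stats = {"lines_read": len(frame), "skipped_malformed": 0}
    for row in frame.itertuples(index=False):
        try:
            chrom = str(row.chrom)
            if strip_chr and chrom.startswith("chr"):
                chrom = chrom[3:]
            n_ref = None if pd.isna(row.n_ref) else int(row.n_ref)
            n_alt = None if pd.isna(row.n_alt) else int(row.n_alt)
            calls.append(MutationCall(
                subject_id=str(row.subject), caller_id=str(row.caller),
                chrom=chrom, pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
                vtype=classify_variant(str(row.ref), str(row.alt)),
                tumor_ref_depth=int(row.t_ref), tumor_alt_depth=int(row.t_alt),
                normal_ref_depth=n_ref, normal_alt_depth=n_alt,
            ))
        except (ValueError, TypeError):
            stats["skipped_malformed"] += 1
    return calls, stats


def build_catalog(config: RunConfig, somatic_only: bool = False,
                  strip_chr: bool = True) -> tuple[MutationCatalog, pd.DataFrame]:
    """Parse every configured file into one catalogue.

    Returns the catalogue plus a per-file parse report (lines read, calls
    kept, malformed lines skipped, records dropped as non-somatic).
    Malformed records are never fatal. ``somatic_only`` drops records whose
    dialect-reported inheritance is germline or LOH.
    """
    catalog = MutationCatalog()
    report_rows = []
    # deterministic processing order regardless of config line order
    for entry in sorted(config.entries, key=lambda e: (e.subject_id, e.caller_id)):
        if entry.caller_id == GENERIC_TSV:
            calls, stats = _parse_generic_tsv(entry, strip_chr)
        else:
            calls, stats = _parse_vcf(entry, strip_chr)
        kept = 0
        nonsomatic = 0
        for call in calls:
            if somatic_only and call.inheritance in ("germline", "LOH"):
                nonsomatic += 1
                continue
            if catalog.add(call):
                kept += 1
        if entry.subject_id not in catalog.subjects:
            catalog.subjects.append(entry.subject_id)
        if entry.caller_id not in catalog.callers:
            catalog.callers.append(entry.caller_id)
        report_rows.append({
            "file": entry.path,
            "lines_read": stats["lines_read"],
            "calls_kept": kept,
            "skipped_malformed": stats["skipped_malformed"],
            "skipped_nonsomatic": nonsomatic,
        })
    report = pd.DataFrame(report_rows, columns=[
        "file", "lines_read", "calls_kept", "skipped_malformed",
        "skipped_nonsomatic"])
    return catalog, report
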