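"""Composable site filters and known-catalogue matching.

Sites that survive multi-caller integration can be screened on consensus
(minimum number of supporting callers), read evidence (tumor alt depth,
tumor/normal VAF), somatic status, membership in an external known-mutation
catalogue (a local MAF-like table), distance to the nearest exon, and
chromosome / variant-type whitelists. Criteria are applied in a fixed order
so the per-criterion attrition report is deterministic.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .core import MutationCatalog, MutationCall, site_key

log = logging.getLogger(__name__)

#: Fixed criterion application order for attrition accounting.
CRITERIA_ORDER = (
    "min_callers", "min_tumor_alt_depth", "min_tumor_vaf", "max_normal_vaf",
    "somatic_only", "require_catalogued", "max_dist_to_exon",
    "chrom_whitelist", "vtype_whitelist",
)

_MAF_COLUMNS = ["Chromosome", "Start_Position", "Reference_Allele",
                "Tumor_Seq_Allele2"]


@dataclass
class FilterSpec:
    """Thresholds of one filtering pass; ``None`` disables a criterion.

    Per-call thresholds (depth, VAF) are met when ANY supporting call
    satisfies them; ``strict_all`` switches to requiring every call to.
    """

    min_callers: int = 1
    min_tumor_alt_depth: Optional[int] = None
    min_tumor_vaf: Optional[float] = None
    max_normal_vaf: Optional[float] = None
    somatic_only: bool = False
    require_catalogued: bool = False
    max_dist_to_exon: Optional[int] = None
    chrom_whitelist: Optional[set[str]] = None
    vtype_whitelist: Optional[set[str]] = None
    strict_all: bool = False

    def __post_init__(self) -> None:
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        for name in ("min_tumor_vaf", "max_normal_vaf"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_tumor_alt_depth is not None and self.min_tumor_alt_depth < 0:
            raise ValueError("min_tumor_alt_depth must be >= 0")
        if self.max_dist_to_exon is not None and self.max_dist_to_exon < 0:
            raise ValueError("max_dist_to_exon must be >= 0")


@dataclass
class KnownSiteCatalogue:
    """Known mutation sites loaded from a MAF-like table."""

    keys: set[str]
    positions: set[tuple[str, int]]
    source: str = "local"

    def __len__(self) -> int:
        return len(self.keys)


def load_known_catalogue(path, source: str = "local",
                         strip_chr: bool = True) -> KnownSiteCatalogue:
    """Read a MAF-like TSV (gzip accepted) into a known-site catalogue.

    Only the columns Chromosome, Start_Position, Reference_Allele and
    Tumor_Seq_Allele2 are used; keys are canonicalized like the main
    catalogue's site keys.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        frame = pd.read_csv(fh, sep="\t", comment="#", low_memory=False)
    missing = [c for c in _MAF_COLUMNS if c not in frame.columns]
    if missing:
        raise IOError(f"{path}: known catalogue lacks columns {missing}")
    keys: set[str] = set()
    positions: set[tuple[str, int]] = set()
    for row in frame.itertuples(index=False):
        chrom = str(getattr(row, "Chromosome"))
        if strip_chr and chrom.startswith("chr"):
            chrom = chrom[3:]
        pos = int(getattr(row, "Start_Position"))
        ref = str(getattr(row, "Reference_Allele"))
        alt = str(getattr(row, "Tumor_Seq_Allele2"))
        keys.add(site_key(chrom, pos, ref, alt))
        positions.add((chrom, pos))
    return KnownSiteCatalogue(keys, positions, source)


def match_catalogue(catalog: MutationCatalog, known: KnownSiteCatalogue,
                    mode: str = "exact") -> dict[tuple[str, str], bool]:
    """Per (subject, site key): is the site present in the known catalogue?

    ``exact`` matches chrom:pos:ref:alt; ``position`` matches chrom:pos only.
    """
    if mode not in ("exact", "position"):
        raise ValueError(f"unknown match mode {mode!r}")
    flags: dict[tuple[str, str], bool] = {}
    for subj, key in catalog.calls:
        if mode == "exact":
            flags[(subj, key)] = key in known.keys
        else:
            chrom, pos, _, _ = key.split(":", 3)
            flags[(subj, key)] = (chrom, int(pos)) in known.positions
    return flags


def _calls_pass(calls: list[MutationCall], predicate, strict: bool) -> bool:
    return all(map(predicate, calls)) if strict else any(map(predicate, calls))


def filter_sites(catalog: MutationCatalog, spec: FilterSpec,
                 distances: Optional[Mapping[str, Optional[int]]] = None,
                 catalogued: Optional[Mapping[tuple[str, str], bool]] = None,
                 ) -> tuple[MutationCatalog, pd.DataFrame]:
    """Apply the filter spec; return the surviving catalogue and attrition.

    A (subject, site) survives when it has >= ``min_callers`` supporting
    callers and each active per-call criterion is met (by at least one call,
    or by all calls under ``strict_all``). The attrition report counts
    removals per criterion in the fixed application order.
    """
    if spec.max_dist_to_exon is not None and distances is None:
        raise ValueError("max_dist_to_exon set but no distances provided")
    if spec.require_catalogued and catalogued is None:
        raise ValueError("require_catalogued set but no catalogue flags provided")

    survivors = set(catalog.calls)
    rows = []
    for criterion in CRITERIA_ORDER:
        removed = set()
        for pair in survivors:
            subj, key = pair
            calls = list(catalog.calls[pair].values())
            ok = True
            if criterion == "min_callers":
                ok = len(calls) >= spec.min_callers
            elif criterion == "min_tumor_alt_depth" and spec.min_tumor_alt_depth is not None:
                ok = _calls_pass(
                    calls, lambda c: c.tumor_alt_depth >= spec.min_tumor_alt_depth,
                    spec.strict_all)
            elif criterion == "min_tumor_vaf" and spec.min_tumor_vaf is not None:
                ok = _calls_pass(
                    calls,
                    lambda c: c.tumor_vaf is not None and c.tumor_vaf >= spec.min_tumor_vaf,
                    spec.strict_all)
            elif criterion == "max_normal_vaf" and spec.max_normal_vaf is not None:
                ok = _calls_pass(
                    calls,
                    lambda c: c.normal_vaf is not None and c.normal_vaf <= spec.max_normal_vaf,
                    spec.strict_all)
            elif criterion == "somatic_only" and spec.somatic_only:
                ok = _calls_pass(
                    calls, lambda c: c.inheritance in ("somatic", "unknown"),
                    spec.strict_all)
            elif criterion == "require_catalogued" and spec.require_catalogued:
                ok = bool(catalogued.get(pair, False))
            elif criterion == "max_dist_to_exon" and spec.max_dist_to_exon is not None:
                d = distances.get(key)
                ok = d is not None and d <= spec.max_dist_to_exon
            elif criterion == "chrom_whitelist" and spec.chrom_whitelist is not None:
                ok = key.split(":", 1)[0] in spec.chrom_whitelist
            elif criterion == "vtype_whitelist" and spec.vtype_whitelist is not None:
                ok = any(c.vtype in spec.vtype_whitelist for c in calls)
            if not ok:
                removed.add(pair)
        survivors -= removed
        rows.append({"criterion": criterion, "removed": len(removed),
                     "remaining": len(survivors)})
    report = pd.DataFrame(rows, columns=["criterion", "removed", "remaining"])
    return catalog.subset(survivors), report


def merged_vcf(catalog: MutationCatalog, path,
               catalogued: Optional[Mapping[tuple[str, str], bool]] = None
               ) -> None:
    """Write one minimal merged VCF record per surviving (subject, site).

    INFO carries SUBJECT, the supporting CALLERS, NCALLERS and CATALOGUED.
    """
    chroms: list[str] = []
    for _, key in catalog.sorted_sites():
        chrom = key.split(":", 1)[0]
        if chrom not in chroms:
            chroms.append(chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SUBJECT,Number=1,Type=String,Description="Subject identifier">\n')
        fh.write('##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers">\n')
        fh.write('##INFO=<ID=NCALLERS,Number=1,Type=Integer,Description="Number of supporting callers">\n')
        fh.write('##INFO=<ID=CATALOGUED,Number=0,Type=Flag,Description="Present in the known-site catalogue">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for subj, key in catalog.sorted_sites():
            chrom, pos, ref, alt = key.split(":", 3)
            callers = sorted(catalog.calls[(subj, key)])
            info = (f"SUBJECT={subj};CALLERS={','.join(callers)};"
                    f"NCALLERS={len(callers)}")
            if catalogued is not None and catalogued.get((subj, key), False):
                info += ";CATALOGUED"
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\n")
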