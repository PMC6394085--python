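"""Core domain types shared by every analysis module.

The unit of observation is a *mutation call*: one (subject, caller, site)
triple with its allelic depths. Calls from all callers are integrated into a
:class:`MutationCatalog`, keyed by subject and by a canonical site key
``chrom:pos:ref:alt`` so that identical variants reported by different
pipelines collapse onto one site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd

#: The six supported variant-calling pipelines plus the generic table input.
CALLERS = ("mutect", "mutect2", "muse", "somaticsniper", "strelka", "varscan2")
GENERIC_TSV = "generic_tsv"
VALID_CALLERS = CALLERS + (GENERIC_TSV,)

#: Callers that emit SNVs only (no INDEL records).
SNV_ONLY_CALLERS = frozenset({"mutect", "muse", "somaticsniper"})

VTYPES = ("SNV", "INS", "DEL", "MNV")
INHERITANCE = ("somatic", "germline", "LOH", "unknown")


class ConfigError(ValueError):
    """Invalid run configuration (duplicate entries, unknown caller...)."""


def site_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical site identifier, identical across callers."""
    return f"{chrom}:{pos}:{ref}:{alt}"


def classify_variant(ref: str, alt: str) -> str:
    """Classify a REF/ALT pair as SNV, INS, DEL or MNV.

    Equal single-base alleles are SNVs; a longer ALT is an insertion and a
    longer REF a deletion (prefix or not — the longer allele decides);
    equal multi-base lengths are MNVs.
    """
    if not ref or not alt:
        raise ValueError("empty allele")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


def compute_vaf(ref_depth: int, alt_depth: int) -> Optional[float]:
    """Variant allele frequency alt/(ref+alt); ``None`` at zero total depth."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("negative read count")
    total = ref_depth + alt_depth
    if total == 0:
        return None
    return alt_depth / total


@dataclass
class MutationCall:
    """One harmonized (subject, caller, site) observation."""

    subject_id: str
    caller_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str = "SNV"
    inheritance: str = "somatic"
    tumor_ref_depth: int = 0
    tumor_alt_depth: int = 0
    normal_ref_depth: Optional[int] = None
    normal_alt_depth: Optional[int] = None
    tumor_vaf: Optional[float] = None
    filter_field: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"invalid alleles {self.ref!r}/{self.alt!r}")
        if self.tumor_ref_depth < 0 or self.tumor_alt_depth < 0:
            raise ValueError("negative tumor read count")
        if self.tumor_vaf is None:
            self.tumor_vaf = compute_vaf(self.tumor_ref_depth, self.tumor_alt_depth)

    @property
    def key(self) -> str:
        return site_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def tumor_total_depth(self) -> int:
        return self.tumor_ref_depth + self.tumor_alt_depth

    @property
    def normal_vaf(self) -> Optional[float]:
        if self.normal_ref_depth is None or self.normal_alt_depth is None:
            return None
        return compute_vaf(self.normal_ref_depth, self.normal_alt_depth)


_TSV_COLUMNS = [
    "subject_id", "caller_id", "chrom", "pos", "ref", "alt", "vtype",
    "inheritance", "tumor_ref_depth", "tumor_alt_depth",
    "normal_ref_depth", "normal_alt_depth", "tumor_vaf", "filter_field",
]


class MutationCatalog:
    """Integrated mutation structure: (subject, site key) -> caller -> call.

    Subjects and callers keep insertion order so that reports are
    deterministic; content is independent of the order calls are added.
    """

    def __init__(self) -> None:
        self.subjects: list[str] = []
        self.callers: list[str] = []
        self.calls: dict[tuple[str, str], dict[str, MutationCall]] = {}

    def __len__(self) -> int:
        return sum(len(v) for v in self.calls.values())

    @property
    def n_sites(self) -> int:
        return len(self.calls)

    def add(self, call: MutationCall) -> bool:
        """Insert a call; returns False when (subject, site, caller) exists."""
        if call.subject_id not in self.subjects:
            self.subjects.append(call.subject_id)
        if call.caller_id not in self.callers:
            self.callers.append(call.caller_id)
        entry = self.calls.setdefault((call.subject_id, call.key), {})
        if call.caller_id in entry:
            return False
        entry[call.caller_id] = call
        return True

    def iter_calls(self) -> Iterator[MutationCall]:
        for entry in self.calls.values():
            yield from entry.values()

    def site_sets(self, subject: Optional[str] = None) -> dict[str, set]:
        """Per-caller site sets.

        Cohort scope uses (subject, key) units so the same variant in two
        subjects counts twice; subject scope uses bare site keys.
        """
        sets: dict[str, set] = {c: set() for c in self.callers}
        for (subj, key), entry in self.calls.items():
            if subject is not None and subj != subject:
                continue
            unit = key if subject is not None else (subj, key)
            for caller in entry:
                sets[caller].add(unit)
        return sets

    def subject_site_sets(self) -> dict[str, dict[str, set]]:
        """caller -> subject -> set of site keys."""
        out: dict[str, dict[str, set]] = {
            c: {s: set() for s in self.subjects} for c in self.callers
        }
        for (subj, key), entry in self.calls.items():
            for caller in entry:
                out[caller][subj].add(key)
        return out

    def subset(self, keep: Iterable[tuple[str, str]]) -> "MutationCatalog":
        """New catalog restricted to the given (subject, key) pairs.

        Subject and caller ordering of the parent is preserved (callers may
        end up with zero calls and are kept, so scopes stay comparable).
        """
        keep = set(keep)
        sub = MutationCatalog()
        sub.subjects = list(self.subjects)
        sub.callers = list(self.callers)
        for pair, entry in self.calls.items():
            if pair in keep:
                sub.calls[pair] = dict(entry)
        return sub

    def sorted_sites(self) -> list[tuple[str, str]]:
        """(subject, key) pairs in deterministic report order."""
        def sortable(pair):
            subj, key = pair
            chrom, pos, ref, alt = key.split(":", 3)
            return (subj, chrom, int(pos), ref, alt)
        return sorted(self.calls, key=sortable)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subj, key in self.sorted_sites():
            for caller in self.callers:
                call = self.calls[(subj, key)].get(caller)
                if call is None:
                    continue
                rows.append({c: getattr(call, c) for c in _TSV_COLUMNS})
        return pd.DataFrame(rows, columns=_TSV_COLUMNS)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MutationCatalog":
        cat = cls()
        for row in frame.itertuples(index=False):
            d = row._asdict()
            for k in ("normal_ref_depth", "normal_alt_depth", "tumor_vaf"):
                if k in d and pd.isna(d[k]):
                    d[k] = None
                elif k != "tumor_vaf" and k in d and d[k] is not None:
                    d[k] = int(d[k])
            cat.add(MutationCall(
                subject_id=str(d["subject_id"]), caller_id=str(d["caller_id"]),
                chrom=str(d["chrom"]), pos=int(d["pos"]),
                ref=str(d["ref"]), alt=str(d["alt"]),
                vtype=str(d.get("vtype", "SNV")),
                inheritance=str(d.get("inheritance", "somatic")),
                tumor_ref_depth=int(d.get("tumor_ref_depth", 0)),
                tumor_alt_depth=int(d.get("tumor_alt_depth", 0)),
                normal_ref_depth=d.get("normal_ref_depth"),
                normal_alt_depth=d.get("normal_alt_depth"),
                tumor_vaf=d.get("tumor_vaf"),
                filter_field=str(d.get("filter_field", "PASS")),
            ))
        return cat

    @classmethod
    def from_tsv(cls, path) -> "MutationCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
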