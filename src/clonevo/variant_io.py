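"""Variant and CNA-segment I/O, timepoint pairing and somatic/constitutional partitioning.

Coordinate conventions: variants are 1-based (VCF), CNA segments are 0-based
half-open (BED).  The TSV dialect is a plain tab-separated table with header

    chrom pos ref alt alt_count depth effect gene coding timepoint patient_id

and one row per (chrom, pos, ref, alt, patient, timepoint).  Rows with
``alt_count == 0`` are legal and encode reference pileups at queried sites
(used for absence calls at other timepoints).
"""

from __future__ import annotations

import dataclasses
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "Timepoint",
    "Effect",
    "LOF_EFFECTS",
    "VariantRecord",
    "CNASegment",
    "PatientCase",
    "read_variant_table",
    "write_variant_table",
    "read_patient_cases",
    "read_cna_bed",
    "write_cna_bed",
    "read_gene_list",
    "partition_somatic_constitutional",
    "correct_af_for_purity",
    "match_variants",
    "normalize_variant",
]


class Timepoint(str, enum.Enum):
    INI = "INI"
    REM = "REM"
    REL = "REL"


class Effect(str, enum.Enum):
    stopgain = "stopgain"
    stoploss = "stoploss"
    frameshift_indel = "frameshift_indel"
    inframe_indel = "inframe_indel"
    missense = "missense"
    splice_donor = "splice_donor"
    splice_acceptor = "splice_acceptor"
    synonymous = "synonymous"
    other = "other"


#: Loss-of-function classes used by the predisposition screen.
LOF_EFFECTS = frozenset(
    {
        Effect.stopgain,
        Effect.stoploss,
        Effect.frameshift_indel,
        Effect.splice_donor,
        Effect.splice_acceptor,
    }
)

_ALLELE_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class VariantRecord:
    """One called variant (or reference pileup) with read support.

    ``af`` is always ``alt_count / depth`` (0.0 at zero depth).  Purity
    correction stores its result in ``af_adjusted`` and sets ``corrected``;
    ``effective_af`` returns the adjusted value when present.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    effect: Effect = Effect.other
    gene: str = ""
    coding: bool = True
    timepoint: Timepoint = Timepoint.INI
    af_adjusted: float | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not (0 <= self.alt_count <= self.depth):
            raise ValidationError(
                f"need 0 <= alt_count <= depth, got {self.alt_count}/{self.depth} "
                f"at {self.chrom}:{self.pos}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not _ALLELE_RE.match(allele):
                raise ValidationError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} is not uppercase ACGT"
                )

    @property
    def af(self) -> float:
        return self.alt_count / self.depth if self.depth > 0 else 0.0

    @property
    def effective_af(self) -> float:
        return self.af_adjusted if self.af_adjusted is not None else self.af

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class CNASegment:
    """Aberrant copy-number segment; 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    state: str  # gain | loss | cnloh
    logratio: float | None = None

    _STATES = ("gain", "loss", "cnloh")

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.start < 0:
            raise ValidationError("segment start must be >= 0")
        if self.state not in self._STATES:
            raise ValidationError(
                f"state {self.state!r} not in {self._STATES}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PatientCase:
    """Matched INI/REM/REL variant sets plus CNA profiles and outcome data."""

    patient_id: str
    variants: dict[Timepoint, list[VariantRecord]] = field(default_factory=dict)
    blast_fraction: dict[Timepoint, float | None] = field(default_factory=dict)
    cna_profiles: dict[Timepoint, list[CNASegment]] = field(default_factory=dict)
    time_to_relapse_days: int | None = None
    event_after_relapse: bool | None = None

    def __post_init__(self) -> None:
        for tp, bf in self.blast_fraction.items():
            if bf is not None and not (0 < bf <= 1):
                raise ValidationError(
                    f"blast_fraction[{tp}] must be in (0,1], got {bf}"
                )

    def timepoint(self, tp: Timepoint) -> list[VariantRecord]:
        return self.variants.get(tp, [])

    def has_timepoints(self, *tps: Timepoint) -> bool:
        return all(tp in self.variants for tp in tps)


# ---------------------------------------------------------------------------
# table I/O

TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "alt_count",
    "depth",
    "effect",
    "gene",
    "coding",
    "timepoint",
    "patient_id",
)


def _record_from_tsv_row(fields: Mapping[str, str]) -> tuple[str, VariantRecord]:
    alt_count = int(fields["alt_count"])
    depth = int(fields["depth"])
    if depth == 0 and alt_count > 0:
        raise ValidationError(
            f"depth 0 with alt_count {alt_count} at {fields['chrom']}:{fields['pos']}"
        )
    rec = VariantRecord(
        chrom=fields["chrom"],
        pos=int(fields["pos"]),
        ref=fields["ref"],
        alt=fields["alt"],
        alt_count=alt_count,
        depth=depth,
        effect=Effect(fields["effect"]),
        gene=fields["gene"],
        coding=fields["coding"].lower() in ("1", "true", "yes"),
        timepoint=Timepoint(fields["timepoint"]),
    )
    return fields["patient_id"], rec


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    patient_id: str | None = None,
) -> list[VariantRecord]:
    """Read a variant table in the TSV dialect or a minimal VCF 4.2 subset.

    The VCF route requires FORMAT/AD and honours the INFO keys EFFECT, GENE,
    CODING, TIMEPOINT and PATIENT; multi-allelic rows are split into one
    record per alternate allele.  When ``patient_id`` is given, rows for
    other patients are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"variant table not found: {path}")
    if dialect == "tsv":
        records = _read_tsv(path)
    elif dialect == "vcf":
        records = _read_vcf(path)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    if patient_id is not None:
        records = [(pid, r) for pid, r in records if pid == patient_id]
    return [r for _, r in records]


def _read_tsv(path: Path) -> list[tuple[str, VariantRecord]]:
    out: list[tuple[str, VariantRecord]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(TSV_COLUMNS) - set(header)
        if missing:
            raise FormatError(f"{path}: missing TSV columns {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            values = line.split("\t")
            if len(values) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
            out.append(_record_from_tsv_row(dict(zip(header, values))))
    return out


def _read_vcf(path: Path) -> list[tuple[str, VariantRecord]]:
    import pysam

    def info_get(info, key: str, default: str) -> str:
        # pysam raises for keys absent from the header; treat those as defaults
        try:
            value = info.get(key, default)
        except (KeyError, ValueError):
            return default
        return default if value is None else str(value)

    out: list[tuple[str, VariantRecord]] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            effect = Effect(info_get(info, "EFFECT", "other"))
            gene = info_get(info, "GENE", "")
            coding = info_get(info, "CODING", "1").lower() in ("1", "true", "yes")
            timepoint = Timepoint(info_get(info, "TIMEPOINT", "INI"))
            patient = info_get(info, "PATIENT", "")
            for sample in rec.samples.values():
                try:
                    ad = sample.get("AD")
                except (KeyError, ValueError):
                    ad = None
                if ad is None or any(x is None for x in ad):
                    raise FormatError(
                        f"{path}: FORMAT/AD missing at {rec.chrom}:{rec.pos}"
                    )
                depth = int(sum(ad))
                for i, alt in enumerate(rec.alts or ()):
                    out.append(
                        (
                            patient,
                            VariantRecord(
                                chrom=rec.chrom,
                                pos=rec.pos,
                                ref=rec.ref,
                                alt=alt,
                                alt_count=int(ad[i + 1]),
                                depth=depth,
                                effect=effect,
                                gene=gene,
                                coding=coding,
                                timepoint=timepoint,
                            ),
                        )
                    )
    return out


def write_variant_table(
    records: Iterable[VariantRecord],
    path: str | Path,
    patient_id: str = "",
) -> None:
    """Write records in the TSV dialect (stable column order, round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    (
                        r.chrom,
                        str(r.pos),
                        r.ref,
                        r.alt,
                        str(r.alt_count),
                        str(r.depth),
                        r.effect.value,
                        r.gene,
                        "1" if r.coding else "0",
                        r.timepoint.value,
                        patient_id,
                    )
                )
                + "\n"
            )


def read_patient_cases(path: str | Path, dialect: str = "tsv") -> dict[str, PatientCase]:
    """Group a cohort variant table into per-patient cases keyed by patient id."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"variant table not found: {path}")
    pairs = _read_tsv(path) if dialect == "tsv" else _read_vcf(path)
    cases: dict[str, PatientCase] = {}
    for pid, rec in pairs:
        case = cases.setdefault(pid, PatientCase(patient_id=pid))
        case.variants.setdefault(rec.timepoint, []).append(rec)
    return cases


def read_cna_bed(path: str | Path) -> list[CNASegment]:
    """Read aberrant segments from BED4+ (`chrom start end state [logratio]`)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"CNA BED not found: {path}")
    segs: list[CNASegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED4+ requires >= 4 columns")
            logratio = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            segs.append(
                CNASegment(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    state=fields[3],
                    logratio=logratio,
                )
            )
    return segs


def write_cna_bed(segments: Iterable[CNASegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            lr = "." if s.logratio is None else repr(s.logratio)
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t{lr}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a gene list: one symbol per line, ``#`` comments and blanks skipped."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"gene list not found: {path}")
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    return genes


# ---------------------------------------------------------------------------
# derivation operations


def partition_somatic_constitutional(
    case: PatientCase,
    rem_af_const: float = 0.30,
    rem_af_absent: float = 0.05,
    min_rem_depth: int = 10,
) -> dict[str, list[VariantRecord]]:
    """Split detected INI/REL variants by their remission status.

    A variant seen at remission with af >= ``rem_af_const`` is constitutional;
    one absent at remission (af < ``rem_af_absent`` at depth >=
    ``min_rem_depth``) is somatic; anything else — including sites with no
    remission pileup — is unevaluable.  The returned buckets
    (``somatic_INI``, ``somatic_REL``, ``constitutional``, ``unevaluable``)
    partition the detected input records exhaustively and disjointly.
    """
    if Timepoint.REM not in case.variants:
        raise ConfigurationError(
            f"{case.patient_id}: remission timepoint required for partitioning"
        )
    rem_by_key = {r.key: r for r in case.timepoint(Timepoint.REM)}
    out: dict[str, list[VariantRecord]] = {
        "somatic_INI": [],
        "somatic_REL": [],
        "constitutional": [],
        "unevaluable": [],
    }
    for tp, somatic_bucket in ((Timepoint.INI, "somatic_INI"), (Timepoint.REL, "somatic_REL")):
        for v in case.timepoint(tp):
            if v.alt_count == 0:
                continue  # pileup row, not a called variant
            rem = rem_by_key.get(v.key)
            if rem is None:
                out["unevaluable"].append(v)
            elif rem.af >= rem_af_const:
                out["constitutional"].append(v)
            elif rem.af < rem_af_absent and rem.depth >= min_rem_depth:
                out[somatic_bucket].append(v)
            else:
                out["unevaluable"].append(v)
    return out


def correct_af_for_purity(
    v: VariantRecord,
    blast_fraction: float,
    trigger_below: float = 0.8,
) -> VariantRecord:
    """Rescale af by blast content for low-purity samples.

    Applies only when ``blast_fraction < trigger_below``; the corrected value
    is capped at 1.0 and stored in ``af_adjusted``.  Idempotent: correcting an
    already-corrected record recomputes from the raw ``af``.
    """
    if not (0 < blast_fraction <= 1):
        raise ValidationError(f"blast_fraction must be in (0,1], got {blast_fraction}")
    if blast_fraction >= trigger_below:
        return v
    return dataclasses.replace(
        v, af_adjusted=min(v.af / blast_fraction, 1.0), corrected=True
    )


def match_variants(
    a: Sequence[VariantRecord],
    b: Sequence[VariantRecord],
) -> dict[str, dict]:
    """Bucket two variant lists into shared / only-a / only-b by (chrom,pos,ref,alt)."""
    amap: dict[tuple, VariantRecord] = {}
    for v in a:
        if v.key in amap:
            raise ValidationError(f"duplicate key in first list: {v.key}")
        amap[v.key] = v
    bmap: dict[tuple, VariantRecord] = {}
    for v in b:
        if v.key in bmap:
            raise ValidationError(f"duplicate key in second list: {v.key}")
        bmap[v.key] = v
    shared = {k: (amap[k], bmap[k]) for k in amap.keys() & bmap.keys()}
    return {
        "shared": shared,
        "only_a": {k: v for k, v in amap.items() if k not in bmap},
        "only_b": {k: v for k, v in bmap.items() if k not in amap},
    }


def normalize_variant(v: VariantRecord, genome=None) -> VariantRecord:
    """Trim shared allele bases and left-align indels against ``genome``.

    ``genome`` is any mapping of chromosome name to an indexable sequence
    (pyfaidx.Fasta records qualify).  Without a genome, alleles are only
    trimmed; matching then falls back to verbatim alleles.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    # trim common suffix, keeping at least one base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if genome is not None and len(ref) != len(alt):
        chrom_seq = genome[v.chrom]
        while pos > 1 and ref[-1] == alt[-1]:
            prev = str(chrom_seq[pos - 2]).upper()  # base at pos-1, 1-based
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
    if (ref, alt, pos) == (v.ref, v.alt, v.pos):
        return v
    return dataclasses.replace(v, ref=ref, alt=alt, pos=pos)
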