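"""Relapse typing of matched diagnosis/relapse pairs.

A relapse is TYPE2 when at least ``min_lost`` clonal diagnosis mutations
(allele frequency >= 0.30) are confidently absent at relapse, TYPE1 when all
evaluated clonal diagnosis mutations persist, and UNEVALUABLE otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigurationError, ValidationError
from .variant_io import (
    PatientCase,
    Timepoint,
    VariantRecord,
    correct_af_for_purity,
    partition_somatic_constitutional,
)

__all__ = [
    "RelapseType",
    "Fate",
    "ClassificationResult",
    "partition_clonality",
    "call_site_fate",
    "classify_relapse",
    "flag_hypermutator",
]

VariantKey = tuple[str, int, str, str]


class RelapseType(str, enum.Enum):
    TYPE1 = "TYPE1"
    TYPE2 = "TYPE2"
    UNEVALUABLE = "UNEVALUABLE"


class Fate(str, enum.Enum):
    PRESERVED = "PRESERVED"
    LOST = "LOST"
    UNEVALUABLE = "UNEVALUABLE"


@dataclass
class ClassificationResult:
    """Outcome of relapse typing for one patient.

    ``preserved``, ``lost`` and ``unevaluable_sites`` partition the somatic
    diagnosis variants; ``gained`` holds relapse-private somatic variants.
    ``n_lost_clonal`` records how many clonal losses support a TYPE2 call.
    """

    patient_id: str
    relapse_type: RelapseType
    preserved: tuple[VariantKey, ...] = ()
    lost: tuple[VariantKey, ...] = ()
    gained: tuple[VariantKey, ...] = ()
    unevaluable_sites: tuple[VariantKey, ...] = ()
    n_clonal_ini: int = 0
    n_subclonal_ini: int = 0
    n_clonal_rel: int = 0
    n_subclonal_rel: int = 0
    n_lost_clonal: int = 0
    n_rel_coding: int = 0
    flags: set[str] = field(default_factory=set)


def partition_clonality(
    variants: Sequence[VariantRecord],
    threshold: float = 0.30,
) -> dict[str, list[VariantRecord]]:
    """Split variants into clonal (effective af >= threshold) and subclonal."""
    if not (0 < threshold < 1):
        raise ValidationError(f"clonality threshold must be in (0,1), got {threshold}")
    out: dict[str, list[VariantRecord]] = {"clonal": [], "subclonal": []}
    for v in variants:
        out["clonal" if v.effective_af >= threshold else "subclonal"].append(v)
    return out


def call_site_fate(
    ini_variant: VariantRecord,
    rel_pileup: tuple[int, int],
    absent_af: float = 0.02,
    min_depth: int = 20,
) -> Fate:
    """Decide whether a diagnosis variant persists at relapse.

    ``rel_pileup`` is (alt_count, depth) at the diagnosis locus in the relapse
    sample.  Absence calls (LOST) additionally require ``min_depth`` coverage;
    shallower absent sites are UNEVALUABLE.
    """
    alt, depth = rel_pileup
    if alt < 0 or depth < 0 or alt > depth:
        raise ValidationError(f"bad relapse pileup ({alt}, {depth}) for {ini_variant.key}")
    if depth == 0:
        return Fate.UNEVALUABLE
    af = alt / depth
    if af >= absent_af:
        return Fate.PRESERVED
    if depth >= min_depth:
        return Fate.LOST
    return Fate.UNEVALUABLE


def classify_relapse(
    case: PatientCase,
    min_lost: int = 1,
    clonal_threshold: float = 0.30,
    absent_af: float = 0.02,
    min_depth: int = 20,
    rem_af_const: float = 0.30,
    rem_af_absent: float = 0.05,
    min_rem_depth: int = 10,
    purity_trigger: float = 0.8,
    low_blast_warn: float = 0.2,
    hypermutator_threshold: int = 85,
) -> ClassificationResult:
    """Classify one matched case as TYPE1 / TYPE2 / UNEVALUABLE.

    Pipeline: somatic/constitutional partition against the remission sample,
    purity correction of low-blast timepoints, clonality partition at
    diagnosis, per-site fate calls against relapse pileups, then the
    min-lost rule. Relapse-private gains are derived symmetrically from
    diagnosis pileups.
    """
    for tp in (Timepoint.INI, Timepoint.REL):
        if tp not in case.variants:
            raise ConfigurationError(f"{case.patient_id}: missing {tp.value} timepoint")

    partition = partition_somatic_constitutional(
        case, rem_af_const=rem_af_const, rem_af_absent=rem_af_absent,
        min_rem_depth=min_rem_depth,
    )
    flags: set[str] = set()

    def maybe_correct(records: list[VariantRecord], tp: Timepoint) -> list[VariantRecord]:
        bf = case.blast_fraction.get(tp)
        if bf is None or bf >= purity_trigger:
            return records
        flags.add("purity_corrected")
        if bf < low_blast_warn:
            flags.add("low_blast")
        return [correct_af_for_purity(v, bf, trigger_below=purity_trigger) for v in records]

    somatic_ini = maybe_correct(partition["somatic_INI"], Timepoint.INI)
    somatic_rel = maybe_correct(partition["somatic_REL"], Timepoint.REL)

    ini_clonality = partition_clonality(somatic_ini, clonal_threshold)
    rel_clonality = partition_clonality(somatic_rel, clonal_threshold)
    clonal_keys = {v.key for v in ini_clonality["clonal"]}

    rel_pileups: Mapping[VariantKey, VariantRecord] = {
        r.key: r for r in case.timepoint(Timepoint.REL)
    }
    ini_pileups: Mapping[VariantKey, VariantRecord] = {
        r.key: r for r in case.timepoint(Timepoint.INI)
    }

    preserved: list[VariantKey] = []
    lost: list[VariantKey] = []
    unevaluable: list[VariantKey] = []
    n_lost_clonal = 0
    n_clonal_evaluated = 0
    for v in somatic_ini:
        pile = rel_pileups.get(v.key)
        fate = (
            Fate.UNEVALUABLE
            if pile is None
            else call_site_fate(v, (pile.alt_count, pile.depth), absent_af, min_depth)
        )
        if fate is Fate.PRESERVED:
            preserved.append(v.key)
        elif fate is Fate.LOST:
            lost.append(v.key)
        else:
            unevaluable.append(v.key)
        if v.key in clonal_keys:
            if fate is Fate.LOST:
                n_lost_clonal += 1
            if fate is not Fate.UNEVALUABLE:
                n_clonal_evaluated += 1
            elif fate is Fate.UNEVALUABLE:
                flags.add("low_coverage_losses")

    ini_detected_keys = {v.key for v in somatic_ini}
    gained: list[VariantKey] = []
    n_rel_coding = 0
    for v in somatic_rel:
        if v.key in ini_detected_keys:
            continue
        pile = ini_pileups.get(v.key)
        if pile is None:
            absent_at_ini = True
        else:
            fate_at_ini = call_site_fate(
                v, (pile.alt_count, pile.depth), absent_af, min_depth
            )
            absent_at_ini = fate_at_ini is Fate.LOST
        if absent_at_ini:
            gained.append(v.key)

    preserved_set = set(preserved)
    for v in somatic_rel:
        if v.coding and (v.key in preserved_set or v.key in set(gained)):
            n_rel_coding += 1

    if n_lost_clonal >= min_lost:
        relapse_type = RelapseType.TYPE2
    elif clonal_keys and n_clonal_evaluated > 0 and n_lost_clonal == 0:
        relapse_type = RelapseType.TYPE1
    else:
        relapse_type = RelapseType.UNEVALUABLE

    result = ClassificationResult(
        patient_id=case.patient_id,
        relapse_type=relapse_type,
        preserved=tuple(preserved),
        lost=tuple(lost),
        gained=tuple(gained),
        unevaluable_sites=tuple(unevaluable),
        n_clonal_ini=len(ini_clonality["clonal"]),
        n_subclonal_ini=len(ini_clonality["subclonal"]),
        n_clonal_rel=len(rel_clonality["clonal"]),
        n_subclonal_rel=len(rel_clonality["subclonal"]),
        n_lost_clonal=n_lost_clonal,
        n_rel_coding=n_rel_coding,
        flags=flags,
    )
    flag_hypermutator(result, threshold=hypermutator_threshold)
    return result


def flag_hypermutator(result: ClassificationResult, threshold: int = 85) -> bool:
    """Flag cases with strictly more than ``threshold`` coding mutations at relapse."""
    is_hyper = result.n_rel_coding > threshold
    if is_hyper:
        result.flags.add("hypermutator")
    else:
        result.flags.discard("hypermutator")
    return is_hyper
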