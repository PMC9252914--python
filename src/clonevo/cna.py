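"""Concordance of copy-number / CN-LOH profiles between diagnosis and relapse.

Two segments are "the same" when they carry the same aberration state and
reciprocally overlap by at least ``min_ro`` (default 0.5).  Loss of at least
one diagnosis segment at relapse marks a profile loss, used as independent
confirmation of a TYPE2 call.
"""

from __future__ import annotations

import warnings
from typing import Sequence

from .clonal import ClassificationResult, RelapseType
from .errors import ValidationError
from .variant_io import CNASegment

__all__ = ["reciprocal_overlap", "compare_profiles", "confirm_type2"]


def reciprocal_overlap(a: CNASegment, b: CNASegment) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint or on different chromosomes."""
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("zero-length segment")
    if a.chrom != b.chrom:
        return 0.0
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return 0.0
    return min(overlap / len(a), overlap / len(b))


def _check_non_overlapping(segments: Sequence[CNASegment], label: str) -> None:
    by_chrom: dict[str, list[CNASegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"{label}: overlapping segments on {chrom}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )


def compare_profiles(
    ini: Sequence[CNASegment],
    rel: Sequence[CNASegment],
    min_ro: float = 0.5,
) -> dict:
    """Partition segments into retained / lost / gained and flag profile loss.

    A diagnosis segment is retained iff some relapse segment of the same state
    reciprocally overlaps it by >= ``min_ro``; relapse segments with no such
    diagnosis partner are gained.  ``profile_loss`` is true iff any diagnosis
    segment was lost.
    """
    _check_non_overlapping(ini, "INI")
    _check_non_overlapping(rel, "REL")
    retained: list[CNASegment] = []
    lost: list[CNASegment] = []
    for a in ini:
        if any(
            b.state == a.state and reciprocal_overlap(a, b) >= min_ro for b in rel
        ):
            retained.append(a)
        else:
            lost.append(a)
    gained = [
        b
        for b in rel
        if not any(
            a.state == b.state and reciprocal_overlap(a, b) >= min_ro for a in ini
        )
    ]
    return {
        "retained": retained,
        "lost": lost,
        "gained": gained,
        "profile_loss": bool(lost),
    }


def confirm_type2(
    classification: ClassificationResult,
    comparison: dict,
    comparison_patient_id: str | None = None,
) -> ClassificationResult:
    """Set the CNA-confirmation flag on a TYPE2 call when the profile was lost.

    A TYPE1 call paired with a lost profile is discordant and only raises a
    warning (the flag stays unset).
    """
    if (
        comparison_patient_id is not None
        and comparison_patient_id != classification.patient_id
    ):
        raise ValidationError(
            f"patient-id mismatch: classification {classification.patient_id!r} "
            f"vs CNA comparison {comparison_patient_id!r}"
        )
    profile_loss = bool(comparison.get("profile_loss"))
    if classification.relapse_type is RelapseType.TYPE2 and profile_loss:
        classification.flags.add("cna_confirmed_type2")
    elif classification.relapse_type is RelapseType.TYPE1 and profile_loss:
        warnings.warn(
            f"{classification.patient_id}: CNA profile loss in a TYPE1 call "
            "(discordant evidence)",
            stacklevel=2,
        )
    return classification
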