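"""Constitutional cancer-predisposition screening of remission variants."""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .stats import ContingencyTable2x2
from .variant_io import LOF_EFFECTS, VariantRecord

__all__ = ["filter_cpg_variants", "carrier_table"]


def filter_cpg_variants(
    rem_variants: Sequence[VariantRecord],
    gene_list: Iterable[str],
    af_min: float = 0.30,
) -> list[VariantRecord]:
    """Retain constitutional loss-of-function variants in listed genes.

    Keeps exactly the variants with af >= ``af_min``, a truncating or
    canonical-splice effect (stopgain/stoploss, frameshift indel, splice
    donor/acceptor) and a gene on the predisposition list.  Pure predicate:
    order-preserving, idempotent, output subset of input.
    """
    genes = set(gene_list)
    if not genes:
        raise ConfigurationError("empty predisposition gene list")
    return [
        v
        for v in rem_variants
        if v.af >= af_min and v.effect in LOF_EFFECTS and v.gene in genes
    ]


def carrier_table(cases: Sequence[tuple[str, str, int]]) -> ContingencyTable2x2:
    """Cross-tabulate carrier status (>=1 retained variant) by relapse type.

    ``cases`` holds (patient_id, relapse_type, n_retained_variants) triples;
    relapse_type must be TYPE1 or TYPE2 — UNEVALUABLE cases are dropped with
    a warning naming them.  Rows are (TYPE1, TYPE2), columns are
    (carrier, non-carrier), so 0/18 vs 7/20 gives [[0,18],[7,13]].
    """
    dropped = [pid for pid, t, _ in cases if t not in ("TYPE1", "TYPE2")]
    if dropped:
        warnings.warn(
            f"dropping unclassifiable cases from carrier table: {dropped}",
            stacklevel=2,
        )
    a = sum(1 for _, t, n in cases if t == "TYPE1" and n >= 1)
    b = sum(1 for _, t, n in cases if t == "TYPE1" and n == 0)
    c = sum(1 for _, t, n in cases if t == "TYPE2" and n >= 1)
    d = sum(1 for _, t, n in cases if t == "TYPE2" and n == 0)
    return ContingencyTable2x2(a, b, c, d)
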