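"""Detection of putative gene-conversion "SNP flip-over" events.

A flip-over candidate is an individual whose two parental haplotypes for a
segment are a common haplotype and a rare "acceptor" haplotype differing
from it at exactly one site (Hamming distance 1). Because the remaining
sites match, the individual is homozygous everywhere except the acceptor
site — a configuration that statistical phasing cannot get wrong, which is
what makes these events trustworthy in phased population data.

The base change is read common -> rare (the rare haplotype is taken as the
derived, converted product) and classified by the weak/strong partition of
bases: weak W = {A, T}, strong S = {G, C}. W->S changes are AT->GC, S->W
are GC->AT, and W->W or S->S changes leave the GC content unchanged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from gcflip.haplotype_catalog import HaplotypeCatalog
from gcflip.variant_io import SampleSet

__all__ = [
    "ChangeClass",
    "FlipoverEvent",
    "hamming",
    "classify_change",
    "detect_in_individual",
    "scan_population",
    "occurrence_bounds",
    "distinct_acceptor_count",
    "write_events_tsv",
]

WEAK = frozenset("AT")
STRONG = frozenset("GC")

#: Fig-2-style acceptor-occurrence categories -> (min, max) occurrence.
OCCURRENCE_CATEGORIES = {
    "1": (1, 1),
    "2": (2, 2),
    "1-2": (1, 2),
    "1-5": (1, 5),
}


class ChangeClass(str, enum.Enum):
    AT_TO_GC = "AT_to_GC"
    GC_TO_AT = "GC_to_AT"
    NO_BASE_CHANGE = "no_base_change"


@dataclass(frozen=True, slots=True)
class FlipoverEvent:
    """One putative gBGC event: individual, segment, acceptor site, change."""

    individual_id: str
    chrom: str
    segment_index: int
    acceptor_index: int  # 0-based offset within the segment's variant string
    acceptor_pos: int  # 1-based genomic position
    common_allele: str
    rare_allele: str
    change_class: ChangeClass
    acceptor_occurrence: int
    common_occurrence: int


def hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def classify_change(common_allele: str, rare_allele: str) -> ChangeClass:
    """Classify a common -> rare base change by the weak/strong partition."""
    for base in (common_allele, rare_allele):
        if base not in WEAK and base not in STRONG:
            raise ValueError(f"invalid base {base!r}")
    if common_allele == rare_allele:
        raise ValueError("common and rare alleles must differ")
    if common_allele in WEAK and rare_allele in STRONG:
        return ChangeClass.AT_TO_GC
    if common_allele in STRONG and rare_allele in WEAK:
        return ChangeClass.GC_TO_AT
    return ChangeClass.NO_BASE_CHANGE


def detect_in_individual(
    hap_a: str,
    hap_b: str,
    catalog: HaplotypeCatalog,
    individual_id: str = "",
) -> tuple[Optional[FlipoverEvent], str]:
    """Test one individual's parental haplotype pair for a flip-over.

    An event is emitted iff, unordered, one haplotype is common
    (count >= common_min), the other is rare (count <= rare_max), the two
    differ at exactly one position, and the differing variant is a SNP.
    The comparison is strictly within the individual — their two parental
    haplotypes — which enforces the all-but-one-site homozygosity that
    guards against phasing errors.

    Returns ``(event, "ok")`` or ``(None, reason)`` with reason in
    {"identical", "distance", "occurrence", "acceptor_not_snp"}.
    """
    d = hamming(hap_a, hap_b)
    if d == 0:
        return None, "identical"
    if d > 1:
        return None, "distance"
    count_a = catalog.count_of(hap_a)
    count_b = catalog.count_of(hap_b)
    if count_a >= catalog.common_min and count_b <= catalog.rare_max:
        common_hap, rare_hap = hap_a, hap_b
        common_count, rare_count = count_a, count_b
    elif count_b >= catalog.common_min and count_a <= catalog.rare_max:
        common_hap, rare_hap = hap_b, hap_a
        common_count, rare_count = count_b, count_a
    else:
        return None, "occurrence"
    idx = next(i for i, (x, y) in enumerate(zip(common_hap, rare_hap)) if x != y)
    variant = catalog.segment.variants[idx]
    if not variant.is_snp:
        return None, "acceptor_not_snp"
    common_allele = variant.ref_allele if common_hap[idx] == "0" else variant.alt_allele
    rare_allele = variant.ref_allele if rare_hap[idx] == "0" else variant.alt_allele
    event = FlipoverEvent(
        individual_id=individual_id,
        chrom=catalog.segment.chrom,
        segment_index=catalog.segment.index,
        acceptor_index=idx,
        acceptor_pos=variant.pos,
        common_allele=common_allele,
        rare_allele=rare_allele,
        change_class=classify_change(common_allele, rare_allele),
        acceptor_occurrence=rare_count,
        common_occurrence=common_count,
    )
    return event, "ok"


def occurrence_bounds(category: str) -> tuple[int, int]:
    """(min, max) acceptor occurrence for a named category."""
    try:
        return OCCURRENCE_CATEGORIES[category]
    except KeyError:
        raise ValueError(
            f"unknown occurrence category {category!r}; "
            f"expected one of {sorted(OCCURRENCE_CATEGORIES)}"
        ) from None


def scan_population(
    catalogs: Iterable[HaplotypeCatalog],
    samples: SampleSet,
    category: str = "1-5",
) -> list[FlipoverEvent]:
    """Run the detector over every (individual, segment) pair.

    Keeps events whose acceptor-haplotype occurrence falls in ``category``
    (one of "1", "2", "1-2", "1-5"); each qualifying individual contributes
    one event per segment. Output order is deterministic: (chrom, segment
    index, sample order).
    """
    lo, hi = occurrence_bounds(category)
    cats = sorted(catalogs, key=lambda c: (c.segment.chrom, c.segment.index))
    events: list[FlipoverEvent] = []
    for cat in cats:
        if cat.rare_max < hi:
            raise ValueError(
                f"catalog rare_max={cat.rare_max} below category upper bound {hi}"
            )
        by_indiv = cat.haplotypes_by_individual()
        for sample_id in samples.sample_ids:
            hap_a, hap_b = by_indiv[sample_id]
            event, _ = detect_in_individual(hap_a, hap_b, cat, sample_id)
            if event is not None and lo <= event.acceptor_occurrence <= hi:
                events.append(event)
    return events


def distinct_acceptor_count(events: Sequence[FlipoverEvent]) -> int:
    """Number of distinct acceptor haplotypes behind a set of events.

    Complements the default per-carrier counting: an acceptor haplotype
    shared by j carriers produces j events but one distinct acceptor,
    keyed by (chrom, segment, acceptor position, rare allele).
    """
    return len(
        {(e.chrom, e.segment_index, e.acceptor_pos, e.rare_allele) for e in events}
    )


def write_events_tsv(events: Iterable[FlipoverEvent], out) -> None:
    """Serialize events as TSV, one row per (individual, segment) event."""
    out.write(
        "chrom\tsegment\tacceptor_pos\tindividual\tcommon_allele\trare_allele\t"
        "change_class\tacceptor_occurrence\tcommon_occurrence\n"
    )
    for e in events:
        out.write(
            f"{e.chrom}\t{e.segment_index}\t{e.acceptor_pos}\t{e.individual_id}\t"
            f"{e.common_allele}\t{e.rare_allele}\t{e.change_class.value}\t"
            f"{e.acceptor_occurrence}\t{e.common_occurrence}\n"
        )
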