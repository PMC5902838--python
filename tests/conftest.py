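"""Shared fixtures: in-memory toy populations and generated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from gcflip.haplotype_catalog import Segment, rank_haplotypes
from gcflip.variant_io import SampleSet, VariantRecord


def make_population(
    allele_matrix: np.ndarray,
    ref_alt: list[tuple[str, str]] | None = None,
    chrom: str = "1",
    segment_index: int = 1,
    start_pos: int = 1000,
    spacing: int = 500,
):
    """Build (Segment, SampleSet) from an allele matrix.

    ``allele_matrix`` has shape (k variants, N individuals, 2 parental
    alleles) with entries in {0, 1}. Allele frequencies in the records are
    computed from the genotypes.
    """
    k, n, _ = allele_matrix.shape
    if ref_alt is None:
        ref_alt = [("A", "G")] * k
    samples = SampleSet(sample_ids=tuple(f"I{i:03d}" for i in range(n)))
    variants = []
    for vi in range(k):
        alleles = tuple(
            (int(allele_matrix[vi, i, 0]), int(allele_matrix[vi, i, 1]))
            for i in range(n)
        )
        af = float(allele_matrix[vi].sum()) / (2 * n)
        variants.append(
            VariantRecord(
                chrom=chrom,
                pos=start_pos + vi * spacing,
                ref_allele=ref_alt[vi][0],
                alt_allele=ref_alt[vi][1],
                af=af,
                sample_alleles=alleles,
            )
        )
    segment = Segment(chrom=chrom, index=segment_index, variants=tuple(variants))
    return segment, samples


def catalog_from_matrix(allele_matrix, common_min=5, rare_max=2, **kwargs):
    """Segment + catalog + samples from an allele matrix, small thresholds."""
    from gcflip.haplotype_catalog import extract_haplotypes

    segment, samples = make_population(allele_matrix, **kwargs)
    haps = extract_haplotypes(segment, samples)
    catalog = rank_haplotypes(
        segment, haps, samples, common_min=common_min, rare_max=rare_max
    )
    return segment, samples, haps, catalog


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    """A 200-individual, 10-segment population with 9 planted events."""
    from gcflip.flipover_detector import ChangeClass
    from gcflip.synthetic_data import PlantedEvent, SimulationConfig, generate

    config = SimulationConfig(
        seed=123,
        n_individuals=200,
        n_segments=10,
        planted_events=(
            PlantedEvent(1, 25, 0, ChangeClass.AT_TO_GC, 1),
            PlantedEvent(2, 10, 1, ChangeClass.GC_TO_AT, 1),
            PlantedEvent(3, 0, 2, ChangeClass.NO_BASE_CHANGE, 1),
            PlantedEvent(4, 49, 0, ChangeClass.AT_TO_GC, 2),
            PlantedEvent(7, 30, 1, ChangeClass.AT_TO_GC, 3),
            PlantedEvent(9, 12, 2, ChangeClass.GC_TO_AT, 1),
        ),
    )
    return generate(config, tmp_path_factory.mktemp("planted"))
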