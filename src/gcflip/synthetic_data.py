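"""Ground-truthed synthetic inputs for the flip-over pipeline.

Emulates the haplotype structure the detector assumes: each segment's
population of 2N phased haplotypes is dominated by a few high-frequency
founder haplotypes, pairwise at least 3 mismatches apart so that no two
founders can mimic a conversion pair, with rare Hamming-distance-1
"acceptor" haplotypes planted at known sites in known carriers. The
output is a valid reference FASTA plus a phased multi-sample VCF v4.1
with AF INFO tags, together with the exact list of events the detector
should recover.

The generator makes no attempt at coalescent realism — no recombination
maps, no mutation-rate heterogeneity. Its structure is the minimum the
detector's contract requires, which is precisely what makes planted-event
recovery a sharp test: sensitivity and precision must both be 1.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from gcflip.flipover_detector import ChangeClass, FlipoverEvent, classify_change

__all__ = [
    "PlantedEvent",
    "SimulationConfig",
    "SyntheticDataset",
    "ConfigError",
    "generate",
    "mutate_to_class",
    "write_ground_truth_tsv",
]

WEAK_BASES = ("A", "T")
STRONG_BASES = ("G", "C")

#: GC profile: a single fraction, or (start, end, gc) pieces in 1-based coords.
GcProfile = Union[float, Sequence[tuple[int, int, float]]]


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class PlantedEvent:
    """Specification of one acceptor haplotype to plant.

    ``n_carriers`` individuals receive the donor founder on one parental
    chromosome and a copy of the donor mutated at ``acceptor_index`` on
    the other — the exact parental configuration the detector requires.
    """

    segment_index: int  # 1-based, matching Segment.index
    acceptor_index: int  # 0-based within the k-variant string
    donor_founder: int  # index into founder_frequencies
    change_class: ChangeClass
    n_carriers: int = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic population."""

    seed: int = 0
    n_individuals: int = 200
    n_segments: int = 10
    k: int = 50
    founder_frequencies: tuple[float, ...] = (0.4, 0.3, 0.3)
    min_founder_distance: int = 3
    planted_events: tuple[PlantedEvent, ...] = ()
    intersite_spacing_bp: int = 1000
    genome_gc: GcProfile = 0.45
    chrom: str = "1"
    indel_sites: tuple[tuple[int, int], ...] = ()  # (segment_index, variant_index)
    noise_carriers_per_segment: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.founder_frequencies) - 1.0) > 1e-9:
            raise ConfigError("founder frequencies must sum to 1")
        if self.min_founder_distance < 3:
            raise ConfigError(
                "min_founder_distance must be >= 3 so a single planted "
                "mutation cannot collide with another founder"
            )
        if self.k < 2 or self.n_segments < 1 or self.n_individuals < 1:
            raise ConfigError("population dimensions must be positive")
        seen = set()
        for ev in self.planted_events:
            if not 1 <= ev.segment_index <= self.n_segments:
                raise ConfigError(f"planted segment {ev.segment_index} out of range")
            if not 0 <= ev.acceptor_index < self.k:
                raise ConfigError(f"acceptor index {ev.acceptor_index} out of range")
            if not 0 <= ev.donor_founder < len(self.founder_frequencies):
                raise ConfigError(f"donor founder {ev.donor_founder} out of range")
            if ev.n_carriers < 1:
                raise ConfigError("n_carriers must be >= 1")
            key = (ev.segment_index, ev.acceptor_index, ev.donor_founder)
            if key in seen:
                raise ConfigError(f"duplicate planted event at {key}")
            seen.add(key)
            if (ev.segment_index, ev.acceptor_index) in set(self.indel_sites):
                raise ConfigError(
                    "planted acceptor coincides with an indel site; the "
                    "detector only accepts SNP acceptors"
                )

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["planted_events"] = [
            {**asdict(ev), "change_class": ev.change_class.value}
            for ev in self.planted_events
        ]
        return json.dumps(d, **kwargs)


@dataclass
class SyntheticDataset:
    """Paths and ground truth of one generated population."""

    fasta_path: Path
    vcf_path: Path
    sample_ids: tuple[str, ...]
    ground_truth: list[FlipoverEvent]
    config: SimulationConfig


def mutate_to_class(
    ref: str, alt: str, target_class: ChangeClass
) -> Optional[tuple[int, int]]:
    """Orient a biallelic SNP so the common->rare change has a target class.

    Returns ``(common_code, rare_code)`` — which of the 0/1 allele codes
    sits on the common haplotype — or ``None`` when the target class is
    infeasible for this ref/alt pair (e.g. a strong<->strong site can only
    yield no_base_change). When both orientations work (no_base_change on
    a weak<->weak or strong<->strong site), the common haplotype carries
    the reference allele, deterministically.
    """
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if classify_change(ref, alt) is target_class:
        return (0, 1)
    if classify_change(alt, ref) is target_class:
        return (1, 0)
    return None


def _gc_at(profile: GcProfile, pos: int, default: float = 0.45) -> float:
    if isinstance(profile, (int, float)):
        return float(profile)
    for start, end, gc in profile:
        if start <= pos <= end:
            return float(gc)
    return default


def _exact_counts(frequencies: Sequence[float], total: int) -> list[int]:
    """Largest-remainder apportionment of `total` among frequencies."""
    raw = [f * total for f in frequencies]
    counts = [int(x) for x in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _founder_matrix(
    rng: np.random.Generator,
    n_founders: int,
    k: int,
    counts_2n: Sequence[int],
    total_2n: int,
    min_distance: int,
    maf_margin: float,
) -> np.ndarray:
    """Founder allele matrix (n_founders x k) with controlled frequencies.

    Each column is a 0/1 pattern over founders whose exact population alt
    frequency lies in [0.25 + margin, 0.75 - margin], so every site stays
    above the frequent-variant cutoff even after planting perturbs a few
    haplotypes. Pairwise founder Hamming distance >= min_distance is
    enforced by resampling.
    """
    lo = 0.25 + maf_margin
    hi = 0.75 - maf_margin
    patterns = []
    for code in range(1, 2**n_founders - 1):
        bits = [(code >> i) & 1 for i in range(n_founders)]
        freq = sum(c for b, c in zip(bits, counts_2n) if b) / total_2n
        if lo <= freq <= hi:
            patterns.append(bits)
    if not patterns:
        raise ConfigError(
            "no founder allele pattern satisfies the frequency band; "
            "adjust founder_frequencies or reduce planted carriers"
        )
    patterns_arr = np.array(patterns, dtype=np.int8)
    for _ in range(200):
        idx = rng.integers(0, len(patterns_arr), size=k)
        mat = patterns_arr[idx].T  # n_founders x k
        ok = True
        for i in range(n_founders):
            for j in range(i + 1, n_founders):
                if int((mat[i] != mat[j]).sum()) < min_distance:
                    ok = False
        if ok:
            return mat
    raise ConfigError(
        "could not draw founders satisfying the distance constraint; "
        "k may be too small for min_founder_distance"
    )


def generate(
    config: SimulationConfig,
    out_dir: str | Path,
    prefix: str = "synthetic",
) -> SyntheticDataset:
    """Write a synthetic reference FASTA + phased VCF with planted events.

    Deterministic under ``config.seed``. Founder haplotypes are assigned
    to the 2N parental chromosomes in exact largest-remainder proportions
    (then shuffled), so founder occurrence counts are reproducible up to
    the planted overrides. AF INFO tags hold the realized (genotype-
    computed) alternative-allele frequencies.

    Returns a :class:`SyntheticDataset` whose ``ground_truth`` lists the
    planted events as :class:`FlipoverEvent` records with the realized
    occurrence counts, directly comparable to detector output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    total_2n = 2 * n
    n_f = len(config.founder_frequencies)
    k = config.k
    m = config.n_segments * k
    sample_ids = tuple(f"S{i:04d}" for i in range(n))

    # --- variant positions -------------------------------------------------
    spacing = config.intersite_spacing_bp
    gaps = rng.integers(max(spacing // 2, 4), spacing * 3 // 2 + 1, size=m)
    positions = 200 + np.cumsum(gaps)
    genome_len = int(positions[-1]) + 200

    # --- per-segment founders and haplotype assignment ---------------------
    counts_2n = _exact_counts(config.founder_frequencies, total_2n)
    carriers_by_segment: dict[int, int] = {}
    for ev in config.planted_events:
        carriers_by_segment[ev.segment_index] = (
            carriers_by_segment.get(ev.segment_index, 0) + ev.n_carriers
        )

    founders: list[np.ndarray] = []  # per segment: n_f x k
    hap_codes: list[np.ndarray] = []  # per segment: 2N x k
    hap_founder_labels: list[np.ndarray] = []
    for seg in range(1, config.n_segments + 1):
        perturb = 2 * carriers_by_segment.get(seg, 0) + config.noise_carriers_per_segment
        margin = max(0.02, (perturb + 1) / total_2n)
        mat = _founder_matrix(
            rng, n_f, k, counts_2n, total_2n,
            config.min_founder_distance, margin,
        )
        founders.append(mat)
        labels = np.repeat(np.arange(n_f), counts_2n)
        rng.shuffle(labels)
        hap_founder_labels.append(labels)
        hap_codes.append(mat[labels].copy())  # 2N x k

    # --- plant acceptor events ---------------------------------------------
    # Each carrier: haplotype 0 (parent 1) = donor founder, haplotype 1
    # (parent 2) = donor mutated at the acceptor site.
    acceptor_meta: list[tuple[PlantedEvent, list[int], int]] = []
    used: dict[int, set[int]] = {seg: set() for seg in range(1, config.n_segments + 1)}
    for ev in config.planted_events:
        seg_i = ev.segment_index - 1
        available = [i for i in range(n) if i not in used[ev.segment_index]]
        if len(available) < ev.n_carriers:
            raise ConfigError("not enough unplanted individuals in segment")
        chosen = sorted(
            rng.choice(len(available), size=ev.n_carriers, replace=False).tolist()
        )
        carriers = [available[c] for c in chosen]
        used[ev.segment_index].update(carriers)
        donor = founders[seg_i][ev.donor_founder]
        donor_code = int(donor[ev.acceptor_index])
        for indiv in carriers:
            hap_codes[seg_i][2 * indiv] = donor
            hap_founder_labels[seg_i][2 * indiv] = ev.donor_founder
            acceptor = donor.copy()
            acceptor[ev.acceptor_index] = 1 - donor_code
            hap_codes[seg_i][2 * indiv + 1] = acceptor
            hap_founder_labels[seg_i][2 * indiv + 1] = -1
        acceptor_meta.append((ev, carriers, donor_code))

    # --- optional noise haplotypes (Hamming >= 2 from every founder) --------
    for seg in range(1, config.n_segments + 1):
        seg_i = seg - 1
        for _ in range(config.noise_carriers_per_segment):
            available = [i for i in range(n) if i not in used[seg]]
            if not available:
                break
            indiv = available[int(rng.integers(0, len(available)))]
            used[seg].add(indiv)
            base_founder = int(rng.integers(0, n_f))
            for _try in range(50):
                noisy = founders[seg_i][base_founder].copy()
                flip = rng.choice(k, size=2, replace=False)
                noisy[flip] = 1 - noisy[flip]
                dists = [(founders[seg_i][f] != noisy).sum() for f in range(n_f)]
                if min(dists) >= 2:
                    break
            hap_codes[seg_i][2 * indiv + 1] = noisy
            hap_founder_labels[seg_i][2 * indiv + 1] = -2

    # --- allele base assignment ---------------------------------------------
    all_bases = "ACGT"
    ref_alleles: list[str] = []
    alt_alleles: list[str] = []
    indel_set = set(config.indel_sites)
    acceptor_lookup = {
        (ev.segment_index, ev.acceptor_index): (ev, donor_code)
        for ev, _, donor_code in acceptor_meta
    }
    for vi in range(m):
        seg_index = vi // k + 1
        within = vi % k
        key = (seg_index, within)
        if key in acceptor_lookup:
            ev, donor_code = acceptor_lookup[key]
            if ev.change_class is ChangeClass.AT_TO_GC:
                common_b = rng.choice(WEAK_BASES)
                rare_b = rng.choice(STRONG_BASES)
            elif ev.change_class is ChangeClass.GC_TO_AT:
                common_b = rng.choice(STRONG_BASES)
                rare_b = rng.choice(WEAK_BASES)
            else:
                pool = WEAK_BASES if rng.random() < 0.5 else STRONG_BASES
                common_b, rare_b = rng.permutation(pool).tolist()
            if donor_code == 0:
                ref, alt = str(common_b), str(rare_b)
            else:
                ref, alt = str(rare_b), str(common_b)
            # common hap carries donor_code, rare carries its complement;
            # the oriented bases must realize the requested class
            assert classify_change(str(common_b), str(rare_b)) is ev.change_class
            assert mutate_to_class(ref, alt, ev.change_class) is not None
        elif key in indel_set:
            anchor = all_bases[int(rng.integers(0, 4))]
            second = all_bases[int(rng.integers(0, 4))]
            ref, alt = anchor + second, anchor  # 2-bp deletion-style indel
        else:
            i0 = int(rng.integers(0, 4))
            i1 = (i0 + 1 + int(rng.integers(0, 3))) % 4
            ref, alt = all_bases[i0], all_bases[i1]
        ref_alleles.append(ref)
        alt_alleles.append(alt)

    # --- reference genome ----------------------------------------------------
    seq = np.empty(genome_len, dtype="<U1")
    rand = rng.random(genome_len)
    half = rng.random(genome_len) < 0.5
    if isinstance(config.genome_gc, (int, float)):
        gc_arr = np.full(genome_len, float(config.genome_gc))
    else:
        gc_arr = np.full(genome_len, 0.45)
        for start, end, gc in config.genome_gc:
            gc_arr[start - 1 : end] = gc
    strong = rand < gc_arr
    seq[strong & half] = "G"
    seq[strong & ~half] = "C"
    seq[~strong & half] = "A"
    seq[~strong & ~half] = "T"
    for vi in range(m):
        pos0 = int(positions[vi]) - 1
        for off, base in enumerate(ref_alleles[vi]):
            seq[pos0 + off] = base

    fasta_path = out_dir / f"{prefix}.fasta"
    with open(fasta_path, "w") as fh:
        fh.write(f">{config.chrom}\n")
        s = "".join(seq.tolist())
        for i in range(0, len(s), 60):
            fh.write(s[i : i + 60] + "\n")
    # drop any stale pyfaidx index for a previous file at this path
    stale_index = Path(str(fasta_path) + ".fai")
    if stale_index.exists():
        stale_index.unlink()

    # --- VCF -----------------------------------------------------------------
    vcf_path = out_dir / f"{prefix}.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write(f"##contig=<ID={config.chrom},length={genome_len}>\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,'
            'Description="Alternative allele frequency">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for vi in range(m):
            seg_i = vi // k
            within = vi % k
            col = hap_codes[seg_i][:, within]
            af = float(col.sum()) / total_2n
            if min(af, 1 - af) <= 0.25:
                raise ConfigError(
                    f"realized MAF {min(af, 1 - af):.4f} at variant {vi} "
                    "fell below the frequent-variant cutoff"
                )
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n)
            )
            fh.write(
                f"{config.chrom}\t{int(positions[vi])}\t.\t{ref_alleles[vi]}\t"
                f"{alt_alleles[vi]}\t.\tPASS\tAF={af:.6f}\tGT\t{gts}\n"
            )

    # --- ground truth --------------------------------------------------------
    ground_truth: list[FlipoverEvent] = []
    for ev, carriers, donor_code in acceptor_meta:
        seg_i = ev.segment_index - 1
        vi = seg_i * k + ev.acceptor_index
        ref, alt = ref_alleles[vi], alt_alleles[vi]
        common_allele = ref if donor_code == 0 else alt
        rare_allele = alt if donor_code == 0 else ref
        donor = founders[seg_i][ev.donor_founder]
        acceptor = donor.copy()
        acceptor[ev.acceptor_index] = 1 - donor_code
        codes = hap_codes[seg_i]
        common_occurrence = int((codes == donor).all(axis=1).sum())
        acceptor_occurrence = int((codes == acceptor).all(axis=1).sum())
        for indiv in carriers:
            ground_truth.append(
                FlipoverEvent(
                    individual_id=sample_ids[indiv],
                    chrom=config.chrom,
                    segment_index=ev.segment_index,
                    acceptor_index=ev.acceptor_index,
                    acceptor_pos=int(positions[vi]),
                    common_allele=common_allele,
                    rare_allele=rare_allele,
                    change_class=ev.change_class,
                    acceptor_occurrence=acceptor_occurrence,
                    common_occurrence=common_occurrence,
                )
            )

    return SyntheticDataset(
        fasta_path=fasta_path,
        vcf_path=vcf_path,
        sample_ids=sample_ids,
        ground_truth=ground_truth,
        config=config,
    )


def write_ground_truth_tsv(events: Sequence[FlipoverEvent], out) -> None:
    """Serialize planted ground truth in the events-TSV column layout."""
    from gcflip.flipover_detector import write_events_tsv

    write_events_tsv(events, out)
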