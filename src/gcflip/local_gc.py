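"""Local GC-content context of conversion sites.

For each putative conversion site, the GC fraction of the reference
sequence in a fixed window around the site (by default 50 bases either
side, excluding the focal base) is computed, and the distribution over
sites of one change class is compared against the distribution around
randomly placed control sites by a chi-square goodness-of-fit test, with
the control as the expected distribution. GC-biased gene conversion
predicts conversion events to be over-represented in GC-rich sequence,
because recombination (and hence heteroduplex formation) is more frequent
there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from gcflip.flipover_detector import FlipoverEvent
from gcflip.variant_io import read_fasta_window

__all__ = [
    "GCDistribution",
    "GofResult",
    "local_gc",
    "sample_random_sites",
    "gc_values_for_sites",
    "compare_distributions",
    "default_bins",
]

#: Maximum tolerated fraction of ambiguous (N) bases in a window.
MAX_N_FRACTION = 0.10


def default_bins(width: float = 0.02) -> np.ndarray:
    """GC-fraction bin edges covering [0, 1] at the given width."""
    n = int(round(1.0 / width))
    return np.linspace(0.0, 1.0, n + 1)


def local_gc(window: str) -> Optional[float]:
    """GC fraction of a window: (G + C) / (non-N bases).

    Returns ``None`` (rejected) when more than 10% of the window is N or
    when no unambiguous base remains.
    """
    if not window:
        raise ValueError("empty window")
    w = window.upper()
    n_amb = w.count("N")
    if n_amb > MAX_N_FRACTION * len(w):
        return None
    denom = len(w) - n_amb
    if denom == 0:
        return None
    return (w.count("G") + w.count("C")) / denom


def sample_random_sites(
    n: int,
    regions: Sequence[tuple[str, int, int]],
    seed: int | np.random.Generator,
) -> list[tuple[str, int]]:
    """Draw ``n`` positions uniformly (with replacement) from region union.

    ``regions`` are (chrom, start, end) with 1-based inclusive bounds —
    typically the spans of the analyzed segments, so that control sites
    share the detector's genomic footprint. Reproducible under ``seed``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not regions:
        raise ValueError("no regions to sample from")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lengths = np.array([end - start + 1 for _, start, end in regions], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("region with non-positive length")
    probs = lengths / lengths.sum()
    sites: list[tuple[str, int]] = []
    if n == 0:
        return sites
    region_idx = rng.choice(len(regions), size=n, p=probs)
    for ridx in region_idx:
        chrom, start, end = regions[ridx]
        pos = int(rng.integers(start, end + 1))
        sites.append((chrom, pos))
    return sites


def gc_values_for_sites(
    sites: Sequence[tuple[str, int]],
    ref,
    flank: int = 50,
    include_focal: bool = False,
) -> tuple[np.ndarray, int]:
    """Window GC fractions for a list of (chrom, pos) sites.

    Returns (values, n_skipped); sites whose window overruns a contig edge
    or is too N-rich are skipped, not imputed.
    """
    values: list[float] = []
    skipped = 0
    for chrom, pos in sites:
        window = read_fasta_window(ref, chrom, pos, flank=flank, include_focal=include_focal)
        if window is None:
            skipped += 1
            continue
        gc = local_gc(window)
        if gc is None:
            skipped += 1
            continue
        values.append(gc)
    return np.asarray(values, dtype=float), skipped


@dataclass(frozen=True)
class GCDistribution:
    """Binned distribution of window GC fractions for one site class."""

    label: str
    bin_edges: np.ndarray
    counts: np.ndarray
    n_sites: int
    n_skipped: int

    @property
    def densities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    @classmethod
    def from_values(
        cls, label: str, values: np.ndarray, bin_edges: np.ndarray, n_skipped: int = 0
    ) -> "GCDistribution":
        counts, _ = np.histogram(values, bins=bin_edges)
        return cls(
            label=label,
            bin_edges=np.asarray(bin_edges, dtype=float),
            counts=counts,
            n_sites=len(values),
            n_skipped=n_skipped,
        )


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness-of-fit of an observed class against the control."""

    label: str
    chi2: float
    df: int
    p_value: float
    n_bins_pooled: int


def _pool_sparse_bins(
    observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent bins until every expected count is >= min_expected."""
    obs: list[float] = []
    exp: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:
        if exp:
            obs[-1] += acc_o
            exp[-1] += acc_e
        else:
            obs.append(acc_o)
            exp.append(acc_e)
    return np.asarray(obs), np.asarray(exp)


def chisq_gof(observed: GCDistribution, control: GCDistribution) -> GofResult:
    """Goodness-of-fit of observed bin counts against the control shape.

    Expected counts are the control densities scaled to the observed total;
    bins with expected count < 5 are pooled with neighbors before testing.
    """
    if observed.n_sites == 0 or control.n_sites == 0:
        raise ValueError("cannot test an empty distribution")
    expected = control.densities * observed.counts.sum()
    obs, exp = _pool_sparse_bins(observed.counts.astype(float), expected)
    keep = exp > 0
    obs, exp = obs[keep], exp[keep]
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = max(len(obs) - 1, 1)
    return GofResult(
        label=observed.label,
        chi2=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df=df)),
        n_bins_pooled=len(obs),
    )


def compare_distributions(
    events_by_class: Mapping[str, Sequence[FlipoverEvent]],
    ref,
    regions: Sequence[tuple[str, int, int]],
    n_control: Optional[int] = None,
    bins: Optional[np.ndarray] = None,
    seed: int = 0,
    flank: int = 50,
    equalize: bool = True,
) -> tuple[dict[str, GCDistribution], dict[str, GofResult]]:
    """Local-GC distributions per change class vs a random control.

    Classes are downsampled (seeded) to the size of the smallest class so
    the comparison is at equal n, and the control draws the same number of
    uniformly random sites from the analyzed regions. Each observed class
    is tested against the control by chi-square goodness-of-fit.

    Returns (distributions, gof_results); the control distribution appears
    under the key ``"control"``. Empty classes are skipped.
    """
    rng = np.random.default_rng(seed)
    bin_edges = default_bins() if bins is None else np.asarray(bins, dtype=float)

    populated = {k: list(v) for k, v in events_by_class.items() if len(v) > 0}
    if not populated:
        raise ValueError("no events in any class")
    n_equal = min(len(v) for v in populated.values()) if equalize else None

    distributions: dict[str, GCDistribution] = {}
    for label in sorted(populated):
        evs = populated[label]
        if n_equal is not None and len(evs) > n_equal:
            idx = rng.choice(len(evs), size=n_equal, replace=False)
            evs = [evs[i] for i in sorted(idx)]
        sites = [(e.chrom, e.acceptor_pos) for e in evs]
        values, skipped = gc_values_for_sites(sites, ref, flank=flank)
        distributions[label] = GCDistribution.from_values(
            label, values, bin_edges, n_skipped=skipped
        )

    if n_control is None:
        n_control = n_equal if n_equal is not None else max(
            len(v) for v in populated.values()
        )
    control_sites = sample_random_sites(n_control, regions, rng)
    control_values, control_skipped = gc_values_for_sites(
        control_sites, ref, flank=flank
    )
    control = GCDistribution.from_values(
        "control", control_values, bin_edges, n_skipped=control_skipped
    )
    distributions["control"] = control

    gof: dict[str, GofResult] = {}
    for label, dist in distributions.items():
        if label == "control" or dist.n_sites == 0:
            continue
        gof[label] = chisq_gof(dist, control)
    return distributions, gof
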