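"""Closed-form per-gamete expectation model for SNP flip-overs.

During meiosis, non-crossover (NCO) and crossover (CO) recombination both
form heteroduplex DNA; heterozygous sites inside a heteroduplex become
mismatches, and mismatch repair resolves each one either back to the
original allele or to the partner allele (a flip-over), with equal
probability under the neutral-resolution assumption. The model multiplies
out: events per generation x mean tract length -> total heteroduplex
length; divided by the mean heterozygous-site spacing -> mismatches;
halved -> realized base changes; split by the empirical outcome fractions
-> expected weak-to-strong, strong-to-weak and no-change events per
gamete, whose difference is the net GC gain per gamete.

Defaults are literature rates for humans: 228 NCOs x 75 bp tracts,
~30 COs x 600 bp tracts, one heterozygous site per 1.2 kb, and the
outcome split 45.7% / 38.9% / 15.4% (AT->GC / GC->AT / no change)
observed in the population scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["GameteModelParams", "GameteModelResult", "evaluate"]


@dataclass(frozen=True)
class GameteModelParams:
    """Rate parameters of the per-gamete model.

    Attributes
    ----------
    nco_events : float
        NCO recombination events per generation (default 228).
    nco_tract_bp : float
        Mean NCO heteroduplex tract length in bp (default 75).
    co_events : float
        Crossovers per generation, sex-averaged (default 30).
    co_tract_bp : float
        Mean CO heteroduplex tract length in bp (default 600).
    het_spacing_bp : float
        Mean distance between heterozygous sites in bp (default 1200).
    resolve_prob : float
        Probability a heteroduplex mismatch resolves as a flip-over
        rather than restoring the original allele (default 0.5).
    frac_ws, frac_sw, frac_none : float
        Outcome fractions of flip-overs: AT->GC, GC->AT, no base change.
        Must sum to 1 (tolerance 1e-3). Can be injected from a
        :class:`~gcflip.bgc_stats.BiasSummary` via ``from_summary``.
    """

    nco_events: float = 228.0
    nco_tract_bp: float = 75.0
    co_events: float = 30.0
    co_tract_bp: float = 600.0
    het_spacing_bp: float = 1200.0
    resolve_prob: float = 0.5
    frac_ws: float = 0.457
    frac_sw: float = 0.389
    frac_none: float = 0.154

    def __post_init__(self) -> None:
        for name in ("nco_events", "nco_tract_bp", "co_events", "co_tract_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.het_spacing_bp <= 0:
            raise ValueError("het_spacing_bp must be positive")
        if not 0.0 <= self.resolve_prob <= 1.0:
            raise ValueError("resolve_prob must lie in [0, 1]")
        total = self.frac_ws + self.frac_sw + self.frac_none
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"outcome fractions sum to {total}, expected 1")

    @classmethod
    def from_summary(cls, summary, **overrides) -> "GameteModelParams":
        """Build params taking the outcome split from a BiasSummary."""
        fractions = summary.class_fractions
        if fractions is None:
            raise ValueError("summary has no events; outcome split undefined")
        return cls(
            frac_ws=fractions["AT_to_GC"],
            frac_sw=fractions["GC_to_AT"],
            frac_none=fractions["no_base_change"],
            **overrides,
        )


@dataclass(frozen=True)
class GameteModelResult:
    """Derived per-gamete expectations (all unrounded)."""

    nco_heteroduplex_kb: float
    co_heteroduplex_kb: float
    nco_mismatches: float
    co_mismatches: float
    flipovers_per_gamete: float  # NCO pathway only (haplotype-visible)
    base_changes_per_gamete: float  # NCO + CO, after resolution
    expected_ws: float
    expected_sw: float
    expected_none: float
    net_gc_gain: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def printed_chain(self, ndigits: int = 1) -> dict[str, float]:
        """The arithmetic chain as conventionally quoted, at ``ndigits``.

        Each quantity is rounded for display, and the per-class
        expectations are recomputed from the *rounded* total so that the
        displayed chain is internally consistent (the figure a reader
        multiplies out is the figure shown): e.g. 14.6 x 0.154 = 2.2,
        whereas the unrounded 14.625 x 0.154 = 2.252 would display as 2.3
        next to a total shown as 14.6.
        """
        base = round(self.base_changes_per_gamete, ndigits)
        ws = self.expected_ws / self.base_changes_per_gamete * base \
            if self.base_changes_per_gamete else 0.0
        sw = self.expected_sw / self.base_changes_per_gamete * base \
            if self.base_changes_per_gamete else 0.0
        none = self.expected_none / self.base_changes_per_gamete * base \
            if self.base_changes_per_gamete else 0.0
        return {
            "nco_heteroduplex_kb": round(self.nco_heteroduplex_kb, ndigits),
            "co_heteroduplex_kb": round(self.co_heteroduplex_kb, ndigits),
            "nco_mismatches": round(self.nco_mismatches, ndigits),
            "co_mismatches": round(self.co_mismatches, ndigits),
            "flipovers_per_gamete": round(self.flipovers_per_gamete, ndigits),
            "base_changes_per_gamete": base,
            "expected_ws": round(ws, ndigits),
            "expected_sw": round(sw, ndigits),
            "expected_none": round(none, ndigits),
            "net_gc_gain": round(ws - sw, ndigits),
        }


def evaluate(params: GameteModelParams = GameteModelParams()) -> GameteModelResult:
    """Evaluate the per-gamete arithmetic chain.

    At the defaults: 228 x 75 bp = 17.1 kb of NCO heteroduplex and
    30 x 600 bp = 18 kb of CO heteroduplex per gamete; 14.25 and 15
    mismatches respectively at one heterozygous site per 1.2 kb; half of
    the NCO mismatches resolve to ~7.1 flip-overs, and NCO + CO together
    give ~14.6 base changes, splitting into ~6.7 AT->GC, ~5.7 GC->AT and
    ~2.2 no-change events — a net gain of ~1 GC pair per gamete.
    """
    nco_bp = params.nco_events * params.nco_tract_bp
    co_bp = params.co_events * params.co_tract_bp
    nco_mm = nco_bp / params.het_spacing_bp
    co_mm = co_bp / params.het_spacing_bp
    flipovers = nco_mm * params.resolve_prob
    base_changes = (nco_mm + co_mm) * params.resolve_prob
    ws = base_changes * params.frac_ws
    sw = base_changes * params.frac_sw
    none = base_changes * params.frac_none
    return GameteModelResult(
        nco_heteroduplex_kb=nco_bp / 1000.0,
        co_heteroduplex_kb=co_bp / 1000.0,
        nco_mismatches=nco_mm,
        co_mismatches=co_mm,
        flipovers_per_gamete=flipovers,
        base_changes_per_gamete=base_changes,
        expected_ws=ws,
        expected_sw=sw,
        expected_none=none,
        net_gc_gain=ws - sw,
    )
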