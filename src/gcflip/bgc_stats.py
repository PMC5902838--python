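"""Substitution-bias statistics over detected flip-over events.

Counts AT->GC (weak-to-strong), GC->AT (strong-to-weak) and no-base-change
events, overall and per chromosome, and quantifies the weak-to-strong
excess:

    bias% = 100 * (n_ws - n_sw) / ((n_ws + n_sw) / 2)

i.e. the difference relative to the mean of the two directional counts.
The standard error of the AT->GC proportion p = n_ws / N uses the rule of
sample proportions, SE = sqrt(p (1 - p) / N) with N = n_ws + n_sw.
Significance of the directional asymmetry is a 1-df chi-square
goodness-of-fit against an equal 50:50 split (inherently two-sided in the
deviation), with an exact binomial test available as a cross-check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from gcflip.flipover_detector import ChangeClass, FlipoverEvent

__all__ = [
    "BiasSummary",
    "bias_excess",
    "proportion_se",
    "chisq_equal_split",
    "binomial_equal_split",
    "summarize",
    "bias_se_delta",
]

#: Display floor for vanishingly small p-values.
P_FLOOR = 1e-16


def bias_excess(n_ws: int, n_sw: int) -> float:
    """Percent excess of weak-to-strong over strong-to-weak events.

    ``100 * (n_ws - n_sw) / ((n_ws + n_sw) / 2)`` — antisymmetric in its
    arguments and zero at parity.
    """
    if n_ws + n_sw <= 0:
        raise ValueError("bias undefined: no directional events")
    return 100.0 * (n_ws - n_sw) / ((n_ws + n_sw) / 2.0)


def proportion_se(n_ws: int, n_sw: int) -> float:
    """Standard error of p = n_ws / N by the rule of sample proportions."""
    n = n_ws + n_sw
    if n <= 0:
        raise ValueError("SE undefined: no directional events")
    p = n_ws / n
    return math.sqrt(p * (1.0 - p) / n)


def bias_se_delta(n_ws: int, n_sw: int) -> float:
    """Delta-method standard error of the bias percentage.

    bias% = 100 * (2p - 1) / 1 ... on the mean-denominator scale
    bias% = 200p - 100, so SE(bias%) = 200 * SE(p). Reported alongside
    SE(p); the appropriate scale depends on how the excess is quoted.
    """
    return 200.0 * proportion_se(n_ws, n_sw)


def chisq_equal_split(a: int, b: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit of (a, b) against an equal split.

    Expected counts are (a+b)/2 each, giving the closed form
    chi2 = (a - b)^2 / (a + b); the p-value is the chi-square survival
    function, two-sided in the deviation by construction.
    """
    n = a + b
    if n <= 0:
        raise ValueError("chi-square undefined: no events")
    chi2 = (a - b) ** 2 / n
    return chi2, float(stats.chi2.sf(chi2, df=1))


def binomial_equal_split(a: int, b: int) -> float:
    """Exact two-sided binomial p-value against p=0.5 (cross-check)."""
    return float(stats.binomtest(a, a + b, 0.5).pvalue)


def _class_counts(events: Sequence[FlipoverEvent]) -> tuple[int, int, int]:
    n_ws = sum(1 for e in events if e.change_class is ChangeClass.AT_TO_GC)
    n_sw = sum(1 for e in events if e.change_class is ChangeClass.GC_TO_AT)
    n_none = sum(1 for e in events if e.change_class is ChangeClass.NO_BASE_CHANGE)
    return n_ws, n_sw, n_none


@dataclass
class BiasSummary:
    """Aggregated flip-over counts and bias statistics for one category."""

    category: str
    n_ws: int
    n_sw: int
    n_none: int
    per_chromosome: pd.DataFrame = field(repr=False)

    @property
    def n_directional(self) -> int:
        return self.n_ws + self.n_sw

    @property
    def n_total(self) -> int:
        return self.n_ws + self.n_sw + self.n_none

    @property
    def p(self) -> Optional[float]:
        """Proportion of AT->GC among directional events."""
        n = self.n_directional
        return self.n_ws / n if n else None

    @property
    def bias_pct(self) -> Optional[float]:
        return bias_excess(self.n_ws, self.n_sw) if self.n_directional else None

    @property
    def se(self) -> Optional[float]:
        return proportion_se(self.n_ws, self.n_sw) if self.n_directional else None

    @property
    def se_bias_pct(self) -> Optional[float]:
        return bias_se_delta(self.n_ws, self.n_sw) if self.n_directional else None

    @property
    def chi2(self) -> Optional[float]:
        if not self.n_directional:
            return None
        return chisq_equal_split(self.n_ws, self.n_sw)[0]

    @property
    def p_value(self) -> Optional[float]:
        if not self.n_directional:
            return None
        return chisq_equal_split(self.n_ws, self.n_sw)[1]

    @property
    def class_fractions(self) -> Optional[dict[str, float]]:
        """Fractions of the three outcome classes among all events."""
        if not self.n_total:
            return None
        t = self.n_total
        return {
            "AT_to_GC": self.n_ws / t,
            "GC_to_AT": self.n_sw / t,
            "no_base_change": self.n_none / t,
        }

    def p_value_display(self) -> str:
        pv = self.p_value
        if pv is None:
            return "undefined"
        return f"<{P_FLOOR:g}" if pv < P_FLOOR else f"{pv:.3g}"

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "n_ws": self.n_ws,
            "n_sw": self.n_sw,
            "n_none": self.n_none,
            "n_total": self.n_total,
            "p": self.p,
            "bias_pct": self.bias_pct,
            "se_p": self.se,
            "se_bias_pct": self.se_bias_pct,
            "chi2": self.chi2,
            "p_value": self.p_value,
            "p_value_display": self.p_value_display(),
            "class_fractions": self.class_fractions,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def summarize(events: Sequence[FlipoverEvent], category: str = "1-5") -> BiasSummary:
    """Aggregate events into class counts and bias statistics.

    Per-chromosome counts mirror the overall tallies (their column sums
    equal the totals); an empty event list yields a zero summary with all
    statistics ``None`` rather than raising.
    """
    n_ws, n_sw, n_none = _class_counts(events)
    rows = []
    for chrom in sorted({e.chrom for e in events}, key=_chrom_key):
        sub = [e for e in events if e.chrom == chrom]
        ws, sw, none = _class_counts(sub)
        rows.append(
            {
                "chrom": chrom,
                "n_ws": ws,
                "n_sw": sw,
                "n_none": none,
                "n_total": ws + sw + none,
            }
        )
    per_chrom = pd.DataFrame(
        rows, columns=["chrom", "n_ws", "n_sw", "n_none", "n_total"]
    )
    return BiasSummary(
        category=category,
        n_ws=n_ws,
        n_sw=n_sw,
        n_none=n_none,
        per_chromosome=per_chrom,
    )


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)
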