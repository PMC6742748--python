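"""Small summary helpers used by the CLI and analysis notebooks."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass


@dataclass(frozen=True)
class FractionSummary:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Percentage rounded to two decimals, the convention used in the
        tabulated summaries (e.g. 683/1,282 -> 53.28)."""
        return round(100.0 * self.numerator / self.denominator, 2)

    def __str__(self) -> str:
        return f"{self.numerator:,}/{self.denominator:,} ({self.percent:.2f}%)"


def fraction_summary(numerator: int, denominator: int) -> FractionSummary:
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return FractionSummary(numerator, denominator)


def category_counts(records) -> dict[str, int]:
    """Category -> count over classified site or TU records."""
    counts = Counter(getattr(r, "category") for r in records)
    if None in counts:
        raise ValueError("unclassified records present")
    return dict(sorted(counts.items()))
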