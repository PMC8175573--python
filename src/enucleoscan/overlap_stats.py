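"""Two-list overlap summaries (Venn counts and percent of union).

Used to reproduce commonly-regulated-gene statistics: given the up- (or
down-) regulated gene lists of two treatments, report how many genes are
shared and what percentage of all altered genes (the union) they make up,
rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

from .screen_stats import round_half_up

__all__ = ["OverlapSummary", "overlap_summary"]


@dataclass(frozen=True)
class OverlapSummary:
    """Venn counts of two identifier lists.

    ``pct_common_of_union`` is ``100 * n_common / n_union`` rounded
    half-up to one decimal; ``None`` (flagged undefined) when the union
    is empty.
    """

    n_a: int
    n_b: int
    n_common: int
    n_union: int
    pct_common_of_union: Optional[float]

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_common) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_common > min(self.n_a, self.n_b):
            raise ValueError("n_common cannot exceed either list size")
        if self.n_union != self.n_a + self.n_b - self.n_common:
            raise ValueError("n_union must equal n_a + n_b - n_common")
        if self.pct_common_of_union is not None and not (
            0.0 <= self.pct_common_of_union <= 100.0
        ):
            raise ValueError("percentage must lie in [0, 100]")


def overlap_summary(
    a: Union[Iterable, Tuple[int, int, int]],
    b: Optional[Iterable] = None,
) -> OverlapSummary:
    """Summarize the overlap of two lists.

    Accepts either two iterables of identifiers (duplicates ignored) or a
    single count triple ``(n_a, n_b, n_common)``.
    """
    if b is None:
        try:
            n_a, n_b, n_common = (int(x) for x in a)
        except (TypeError, ValueError) as exc:
            raise TypeError(
                "supply two identifier collections or one (n_a, n_b, n_common) triple"
            ) from exc
    else:
        set_a, set_b = set(a), set(b)
        n_a, n_b = len(set_a), len(set_b)
        n_common = len(set_a & set_b)
    if n_a < 0 or n_b < 0 or n_common < 0:
        raise ValueError("counts must be non-negative")
    if n_common > min(n_a, n_b):
        raise ValueError("n_common cannot exceed either list size")
    n_union = n_a + n_b - n_common
    pct = round_half_up(100.0 * n_common / n_union, 1) if n_union > 0 else None
    return OverlapSummary(n_a, n_b, n_common, n_union, pct)
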