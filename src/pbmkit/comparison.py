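"""Dataset-level comparisons: CV summaries, set overlaps, split-noise control.

These operations reproduce the study-level sanity checks of a PBM analysis:
how reproducible replicate spots are (coefficient-of-variation summaries),
how bound-sequence sets from different protein sources overlap (2- or 3-set
Venn regions, including comparison against an externally curated reference
list), and how many "differential" calls appear when one group is split at
random against itself — an empirical noise floor for the true between-group
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .differential_binding import DesignSpec, differential_pipeline, select_differential
from .errors import ContractError

__all__ = [
    "OverlapResult",
    "SplitNoiseResult",
    "cv_summary",
    "overlap_sets",
    "reference_overlap",
    "random_split_comparison",
]


@dataclass
class OverlapResult:
    """Exact Venn regions of up to three named sets.

    ``regions`` maps a frozenset of set names to the elements found in
    exactly those sets (and no others); cardinalities therefore sum to the
    union size.
    """

    set_names: tuple[str, ...]
    regions: dict[frozenset, set] = field(default_factory=dict)

    def cardinality(self, *names: str) -> int:
        return len(self.regions.get(frozenset(names), set()))

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def intersection_size(self, *names: str) -> int:
        """Elements present in at least the given sets (classic Venn overlap)."""
        want = frozenset(names)
        return sum(len(v) for k, v in self.regions.items() if want <= k)

    def to_json_dict(self) -> dict:
        return {
            "sets": list(self.set_names),
            "regions": {
                "+".join(sorted(k)): sorted(v) for k, v in self.regions.items()
            },
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "+".join(sorted(k)), "count": len(v)}
            for k, v in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SplitNoiseResult:
    """Outcome of the random-split noise control.

    ``split_count`` is the number of sequences passing the differential
    selection when one group is partitioned at random against itself;
    ``true_count`` the corresponding number for the real between-group
    comparison with identical cutoffs.
    """

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    split_count: int
    true_count: int | None
    seed: int

    @property
    def ratio(self) -> float | None:
        if self.true_count in (None, 0):
            return None
        return self.split_count / self.true_count


def cv_summary(
    cv: pd.DataFrame, cutoffs: Sequence[float] = (5.0, 10.0)
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Fractions of sequences with replicate CV under each cutoff, per channel.

    ``cv`` is the long table produced by ``normalize_arrayset`` with columns
    ``cv_red`` and ``cv_green`` (percent).  Returns the empirical CDF
    evaluated at the cutoffs and full histograms per channel (counts, edges).
    """
    rows = []
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for channel in ("cv_red", "cv_green"):
        values = pd.to_numeric(cv[channel], errors="coerce").dropna().to_numpy()
        if values.size == 0:
            raise ContractError(f"no finite CV values in column '{channel}'")
        for cutoff in cutoffs:
            rows.append(
                {
                    "channel": channel.removeprefix("cv_"),
                    "cutoff_pct": float(cutoff),
                    "fraction_under": float((values < cutoff).mean()),
                }
            )
        counts, edges = np.histogram(values, bins=50)
        hists[channel.removeprefix("cv_")] = (counts, edges)
    return pd.DataFrame(rows), hists


def overlap_sets(named_sets: Mapping[str, Iterable]) -> OverlapResult:
    """Exact membership regions of 2 or 3 named sets."""
    names = tuple(named_sets)
    if not 2 <= len(names) <= 3:
        raise ContractError(f"overlap supports 2 or 3 sets, got {len(names)}")
    sets = {name: set(named_sets[name]) for name in names}
    result = OverlapResult(set_names=names)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            ) if len(combo) < len(names) else set()
            result.regions[frozenset(combo)] = inside - outside
    return result


def reference_overlap(
    selected: Iterable[str], reference: Iterable[str], universe: Iterable[str]
) -> tuple[int, int]:
    """Overlap of a selected set with an external reference list.

    The reference is first restricted to the array universe (only sequences
    actually represented can be recovered), then intersected with the
    selection.  Matching is exact string equality after case folding.
    Returns (on-array reference size, overlap size).
    """
    uni = {str(u).casefold() for u in universe}
    if not uni:
        raise ContractError("empty sequence universe")
    ref_on_array = {str(r).casefold() for r in reference} & uni
    sel = {str(s).casefold() for s in selected}
    return len(ref_on_array), len(ref_on_array & sel)


def random_split_comparison(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    group: str,
    n_per_side: int,
    seed: int,
    m_cutoff: float = 1.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    true_contrast: tuple[str, str] | None = None,
    replicates: int = 1,
) -> list[SplitNoiseResult]:
    """Differential calls between two random halves of one group.

    Slides of ``group`` are partitioned (seeded) into two pseudo-groups of
    ``n_per_side`` slides each and the full two-group differential pipeline
    is run with the same cutoffs as the true comparison, estimating how many
    hits experimental noise alone produces.  When ``true_contrast`` is given
    the true between-group count is computed once and attached to every
    result.  ``replicates`` independent splits are derived from ``seed``.
    """
    groups = list(groups)
    slide_ids = [s for s, g in zip(matrix.columns, groups) if g == group]
    if len(slide_ids) < 2 * n_per_side:
        raise ContractError(
            f"group '{group}' has {len(slide_ids)} slides; "
            f"need >= {2 * n_per_side} for a {n_per_side}v{n_per_side} split"
        )

    true_count: int | None = None
    if true_contrast is not None:
        records = differential_pipeline(
            matrix, DesignSpec(groups=tuple(groups), contrast=true_contrast)
        )
        true_selected, _ = select_differential(
            records, m_cutoff=m_cutoff, alpha=alpha, use_adjusted=use_adjusted
        )
        true_count = len(true_selected)

    rng = np.random.default_rng(seed)
    results: list[SplitNoiseResult] = []
    for _ in range(replicates):
        chosen = rng.choice(len(slide_ids), size=2 * n_per_side, replace=False)
        side_a = tuple(slide_ids[i] for i in chosen[:n_per_side])
        side_b = tuple(slide_ids[i] for i in chosen[n_per_side:])
        sub = matrix.loc[:, list(side_a) + list(side_b)]
        design = DesignSpec(
            groups=("sideA",) * n_per_side + ("sideB",) * n_per_side,
            contrast=("sideA", "sideB"),
        )
        records = differential_pipeline(sub, design)
        selected, _ = select_differential(
            records, m_cutoff=m_cutoff, alpha=alpha, use_adjusted=use_adjusted
        )
        results.append(
            SplitNoiseResult(
                side_a=side_a,
                side_b=side_b,
                split_count=len(selected),
                true_count=true_count,
                seed=seed,
            )
        )
    return results
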