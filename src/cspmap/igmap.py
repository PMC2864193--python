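"""Interval mapping of co-required loci from introgression-line phenotypes.

Each line carries one mapped donor-species segment of the third chromosome,
described by a cytogenetic band interval, plus a binary breakdown flag from
the paternity assay.  The panel's interval endpoints partition the mapped
span into atomic regions; a candidate hypothesis is a small set of regions
that must ALL be introgressed for the phenotype to appear (epistasis between
loci).  Hypotheses are scored by exhaustive enumeration against the observed
flags, and mismatching lines are classified as suppressors (covering but
unaffected) or extra loci (affected without covering).

Region coverage is full coverage: a line only counts as carrying a region if
its segment spans the whole region, since regions are by construction
delimited by introgression endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .bands import CytoBand, CytoInterval

__all__ = [
    "IntrogressionLine",
    "Region",
    "RegionPartition",
    "LocusHypothesis",
    "derive_regions",
    "coverage_matrix",
    "infer_corequired",
    "predict_phenotype",
]

# A cut position: band sort key plus a side marker (0 = just before the band's
# start, 1 = just after its end), so inclusive band intervals segment cleanly.
_Cut = Tuple[int, str, int, int]


@dataclass(frozen=True)
class IntrogressionLine:
    line_id: str
    interval: CytoInterval
    breakdown_flag: Optional[bool] = None

    def _cut_lo(self) -> _Cut:
        return self.interval.start.key_start() + (0,)

    def _cut_hi(self) -> _Cut:
        return self.interval.end.key_end() + (1,)


@dataclass(frozen=True)
class Region:
    """One atomic region of the partition (1-based ``index``)."""

    index: int
    cut_lo: _Cut
    cut_hi: _Cut

    @property
    def label(self) -> str:
        d0, l0, s0, _ = self.cut_lo
        d1, l1, s1, _ = self.cut_hi
        fmt = lambda d, l, s: f"{d}{l}{s}" if 0 < s < 10**6 else f"{d}{l}"
        return f"{fmt(d0, l0, s0)}..{fmt(d1, l1, s1)}"


@dataclass
class RegionPartition:
    """Ordered, disjoint atomic regions covering the mapped span."""

    regions: List[Region]

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def derive_regions(lines: Sequence[IntrogressionLine]) -> RegionPartition:
    """Partition the mapped span at the panel's interval endpoints.

    Atomic segments are delimited by the distinct interval endpoints;
    consecutive segments covered by exactly the same set of lines are merged
    (no endpoint genuinely separates them), and segments covered by no line
    (gaps) are dropped.  Every input interval is then exactly a union of
    whole regions.
    """
    if not lines:
        raise ValueError("need at least one introgression interval")
    cuts = sorted({c for ln in lines for c in (ln._cut_lo(), ln._cut_hi())})
    segments: List[Tuple[_Cut, _Cut, FrozenSet[str]]] = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        # a gap from "just after sub-band s" to "just before sub-band s+1"
        # of the same band contains no position at all -- skip it
        if (lo[3], hi[3]) == (1, 0) and lo[:2] == hi[:2] and hi[2] == lo[2] + 1:
            continue
        cover = frozenset(ln.line_id for ln in lines
                          if ln._cut_lo() <= lo and hi <= ln._cut_hi())
        if cover:
            segments.append((lo, hi, cover))
    merged: List[Tuple[_Cut, _Cut, FrozenSet[str]]] = []
    for lo, hi, cover in segments:
        if merged and merged[-1][2] == cover and merged[-1][1] == lo:
            merged[-1] = (merged[-1][0], hi, cover)
        else:
            merged.append((lo, hi, cover))
    regions = [Region(index=i + 1, cut_lo=lo, cut_hi=hi)
               for i, (lo, hi, _) in enumerate(merged)]
    return RegionPartition(regions=regions)


def coverage_matrix(lines: Sequence[IntrogressionLine],
                    partition: RegionPartition) -> np.ndarray:
    """Boolean (line x region) matrix: entry true iff the line's interval
    fully covers the region."""
    mat = np.zeros((len(lines), len(partition)), dtype=bool)
    for i, ln in enumerate(lines):
        lo, hi = ln._cut_lo(), ln._cut_hi()
        for j, reg in enumerate(partition.regions):
            mat[i, j] = lo <= reg.cut_lo and reg.cut_hi <= hi
    return mat


@dataclass
class LocusHypothesis:
    """A candidate co-required region set with its fit to the observed flags."""

    required_regions: FrozenSet[int]          # 1-based region indices
    n_consistent: int
    exceptions: List[Tuple[str, str]] = field(default_factory=list)  # (line_id, kind)

    @property
    def score(self) -> int:
        return self.n_consistent


def predict_phenotype(hypothesis: LocusHypothesis, coverage_row: np.ndarray) -> bool:
    """Predicted breakdown: true iff the line covers every required region."""
    req = hypothesis.required_regions
    if not req:
        raise ValueError("empty hypothesis is forbidden")
    idx = np.fromiter((r - 1 for r in req), dtype=int)
    return bool(coverage_row[idx].all())


def infer_corequired(coverage: np.ndarray, flags: Sequence[bool],
                     line_ids: Optional[Sequence[str]] = None,
                     max_set_size: int = 3) -> List[LocusHypothesis]:
    """Exhaustively score all region subsets of size 1..max_set_size.

    A hypothesis predicts breakdown for exactly the lines covering all its
    regions; its score is the number of lines whose prediction matches the
    observed flag.  Hypotheses are returned sorted by score (descending),
    then set size (ascending; the minimal co-required set is preferred),
    then lexicographic region order.  Each hypothesis lists its mismatches:
    covering-but-no-breakdown lines as suppressors, breakdown-without-
    covering lines as extra loci.
    """
    if max_set_size < 1:
        raise ValueError("max_set_size must be >= 1")
    coverage = np.asarray(coverage, dtype=bool)
    flags_arr = np.asarray(list(flags), dtype=bool)
    n_lines, k = coverage.shape
    if n_lines != len(flags_arr):
        raise ValueError("coverage rows and flags length differ")
    if not flags_arr.any():
        raise ValueError("need at least one breakdown line")
    if line_ids is None:
        line_ids = [str(i) for i in range(n_lines)]

    hyps: List[LocusHypothesis] = []
    for size in range(1, min(max_set_size, k) + 1):
        for subset in combinations(range(k), size):
            predicted = coverage[:, subset].all(axis=1)
            match = predicted == flags_arr
            exceptions = []
            for i in np.nonzero(~match)[0]:
                kind = "suppressor" if predicted[i] else "extra_locus"
                exceptions.append((str(line_ids[i]), kind))
            hyps.append(LocusHypothesis(
                required_regions=frozenset(r + 1 for r in subset),
                n_consistent=int(match.sum()),
                exceptions=exceptions))
    hyps.sort(key=lambda h: (-h.n_consistent, len(h.required_regions),
                             tuple(sorted(h.required_regions))))
    return hyps
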