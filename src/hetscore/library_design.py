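"""Library-construction informatics: guide selection and colony deconvolution.

Guide selection is rule-based: avoid exon regions that are terminal (first
or last) in more than 25% of the transcripts containing them, require an
on-target activity score of at least 0.7, pick at most one guide per exon
region, and prefer guides shared by the maximal number of transcripts,
breaking ties by score and then guide id. Colony deconvolution assigns a
well its most abundant mapped guide when the well has at least ``min_reads``
mapped reads and the top guide is seen strictly more than ``ratio`` times as
often as the runner-up.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence


@dataclasses.dataclass(frozen=True)
class GuideCandidate:
    guide_id: str
    gene: str
    exon_region_id: str
    on_target_score: float
    transcripts_hit: frozenset[str]

    def __post_init__(self) -> None:
        if not 0.0 <= self.on_target_score <= 1.0:
            raise ValueError(f"on_target_score must be in [0, 1], got {self.on_target_score}")


@dataclasses.dataclass
class GeneModel:
    """Transcript structures of one gene: transcript -> ordered exon regions (5'->3')."""

    gene: str
    transcripts: dict[str, list[str]]

    def __post_init__(self) -> None:
        for tid, exons in self.transcripts.items():
            if len(exons) == 0:
                raise ValueError(f"transcript {tid} of {self.gene} has no exon regions")


@dataclasses.dataclass
class GuideSelection:
    gene: str
    selected: list[GuideCandidate]
    shortfall: int  # how many requested guides could not be filled


def eligible_regions(gene: GeneModel, max_terminal_fraction: float = 0.25) -> set[str]:
    """Exon regions usable for guide placement.

    A region is excluded iff, among the transcripts that contain it, the
    fraction in which it is the first or last exon strictly exceeds
    ``max_terminal_fraction``.
    """
    regions = {r for exons in gene.transcripts.values() for r in exons}
    keep = set()
    for region in regions:
        containing = [ex for ex in gene.transcripts.values() if region in ex]
        terminal = sum(1 for ex in containing if ex[0] == region or ex[-1] == region)
        if terminal / len(containing) <= max_terminal_fraction:
            keep.add(region)
    return keep


def select_guides(
    gene: GeneModel,
    candidates: Sequence[GuideCandidate],
    n_guides: int = 3,
    min_score: float = 0.7,
    max_terminal_fraction: float = 0.25,
) -> GuideSelection:
    """Pick up to ``n_guides`` guides for a gene, one per eligible exon region.

    Primary pool: candidates in eligible regions with score >= min_score
    (inclusive), ranked by (more transcripts hit, higher score, guide id).
    If the pool fills fewer than ``n_guides`` regions, the best-scoring
    below-threshold candidates from remaining eligible regions are used,
    ranked by score alone. Any remaining shortfall is reported, not raised.
    """
    for c in candidates:
        if c.gene != gene.gene:
            raise ValueError(f"candidate {c.guide_id} belongs to {c.gene}, not {gene.gene}")
    regions = eligible_regions(gene, max_terminal_fraction)
    pool = [c for c in candidates if c.exon_region_id in regions]
    primary = sorted(
        (c for c in pool if c.on_target_score >= min_score),
        key=lambda c: (-len(c.transcripts_hit), -c.on_target_score, c.guide_id),
    )
    selected: list[GuideCandidate] = []
    used_regions: set[str] = set()
    for c in primary:
        if len(selected) >= n_guides:
            break
        if c.exon_region_id not in used_regions:
            selected.append(c)
            used_regions.add(c.exon_region_id)
    if len(selected) < n_guides:
        fallback = sorted(
            (c for c in pool if c.on_target_score < min_score),
            key=lambda c: (-c.on_target_score, c.guide_id),
        )
        for c in fallback:
            if len(selected) >= n_guides:
                break
            if c.exon_region_id not in used_regions:
                selected.append(c)
                used_regions.add(c.exon_region_id)
    return GuideSelection(gene=gene.gene, selected=selected, shortfall=max(0, n_guides - len(selected)))


@dataclasses.dataclass
class WellAssignment:
    plate: str
    well: str
    guide: str | None
    top_count: int
    second_count: int
    total_reads: int
    retained: bool
    reason: str


def deconvolve_wells(
    counts: Mapping[tuple[str, str], Mapping[str, int]],
    min_reads: int = 50,
    ratio: float = 5.0,
) -> list[WellAssignment]:
    """Assign each well its dominant guide, or reject it with a reason.

    Retained iff total mapped reads >= min_reads (inclusive) AND the top
    guide count strictly exceeds ratio x the second count (vacuously true
    when there is no second guide).
    """
    out = []
    for (plate, well), gmap in sorted(counts.items()):
        items = sorted(gmap.items(), key=lambda kv: (-kv[1], kv[0]))
        total = sum(v for _, v in items)
        top_guide, top = (items[0] if items else (None, 0))
        second = items[1][1] if len(items) > 1 else 0
        if total < min_reads:
            out.append(WellAssignment(plate, well, None, top, second, total, False,
                                      f"total reads {total} < {min_reads}"))
        elif not top > ratio * second:
            out.append(WellAssignment(plate, well, None, top, second, total, False,
                                      f"top count {top} <= {ratio} x second count {second}"))
        else:
            out.append(WellAssignment(plate, well, top_guide, top, second, total, True, "ok"))
    return out


def rearray_unique(assignments: Sequence[WellAssignment]) -> dict[str, tuple[str, str]]:
    """One well per guide: keep the retained well with the highest top count.

    Ties break toward the lexicographically smaller (plate, well) key. The
    result maps guide -> (plate, well) and is injective by construction.
    """
    best: dict[str, WellAssignment] = {}
    for a in sorted(assignments, key=lambda a: (a.plate, a.well)):
        if not a.retained or a.guide is None:
            continue
        cur = best.get(a.guide)
        if cur is None or a.top_count > cur.top_count:
            best[a.guide] = a
    return {g: (a.plate, a.well) for g, a in sorted(best.items())}
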