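"""Relating predicted sites to domain annotations.

Predicted site pairs partition three ways: both sides overlap some known
annotation (counted as co-occurring domain pairs), neither side does
(candidate novel motifs, reported with peak height and subsequence), or
mixed (one side annotated) — excluded from both tables but logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import DomainAnnotation, Interval, Protein

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoredSite:
    """One predicted site pair, optionally carrying its validation DM."""

    id_a: str
    id_b: str
    range_a: Interval
    range_b: Interval
    peak_height: int
    dm: float | None = None


@dataclass(frozen=True)
class DomainPairCount:
    """An unordered co-occurring domain-name pair and its site count."""

    name_a: str
    name_b: str
    count: int


@dataclass(frozen=True)
class NovelMotifReport:
    """A predicted site with no overlapping annotation on either partner."""

    protein_id: str
    peak_height: int
    subsequence: str


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def best_overlap_domain(
    site: Interval, annotations: Sequence[DomainAnnotation]
) -> DomainAnnotation | None:
    """Annotation with maximal residue overlap with ``site``; None if all zero.

    Ties broken by longer annotation, then lexicographic accession.
    """
    best: DomainAnnotation | None = None
    best_key: tuple | None = None
    for ann in annotations:
        ov = _overlap(site, ann.range)
        if ov == 0:
            continue
        length = ann.range[1] - ann.range[0] + 1
        # maximize overlap, then annotation length; minimize accession
        key = (-ov, -length, ann.accession)
        if best_key is None or key < best_key:
            best, best_key = ann, key
    return best


def domain_pair_counts(
    sites: Sequence[ScoredSite],
    annotations: Mapping[str, Sequence[DomainAnnotation]],
    dm_threshold: float | None = None,
) -> list[DomainPairCount]:
    """Counts of unordered co-occurring domain-name pairs over predicted sites.

    When ``dm_threshold`` is given, only high-confidence sites with
    DM < threshold qualify (every site must then carry a DM). Pairs where
    either side has no overlapping annotation are not counted here. Output
    sorted by descending count, then names.
    """
    counts: dict[tuple[str, str], int] = {}
    for site in sites:
        if dm_threshold is not None:
            if site.dm is None:
                raise ValueError(
                    f"site ({site.id_a}, {site.id_b}) lacks a DM but a "
                    "dm_threshold was requested"
                )
            if not site.dm < dm_threshold:
                continue
        dom_a = best_overlap_domain(site.range_a, annotations.get(site.id_a, ()))
        dom_b = best_overlap_domain(site.range_b, annotations.get(site.id_b, ()))
        if dom_a is None or dom_b is None:
            continue
        key = tuple(sorted((dom_a.name, dom_b.name)))
        counts[key] = counts.get(key, 0) + 1
    return sorted(
        (DomainPairCount(a, b, n) for (a, b), n in counts.items()),
        key=lambda r: (-r.count, r.name_a, r.name_b),
    )


def unannotated_sites(
    sites: Sequence[ScoredSite],
    annotations: Mapping[str, Sequence[DomainAnnotation]],
    proteome: Mapping[str, Protein],
) -> list[NovelMotifReport]:
    """Candidate novel motifs: site pairs clean of annotations on both sides.

    One report row per protein side, carrying the landscape peak height and
    the literal predicted subsequence; sorted by descending peak height.
    Mixed pairs (one side annotated) go to neither table and are logged.
    """
    reports: list[NovelMotifReport] = []
    n_mixed = 0
    for site in sites:
        clean_a = all(
            _overlap(site.range_a, ann.range) == 0
            for ann in annotations.get(site.id_a, ())
        )
        clean_b = all(
            _overlap(site.range_b, ann.range) == 0
            for ann in annotations.get(site.id_b, ())
        )
        if clean_a and clean_b:
            for pid, rng in ((site.id_a, site.range_a), (site.id_b, site.range_b)):
                seq = proteome[pid].sequence[rng[0] - 1:rng[1]]
                reports.append(NovelMotifReport(pid, site.peak_height, seq))
        elif clean_a or clean_b:
            n_mixed += 1
            logger.info(
                "site (%s, %s): one side annotated, one clean — excluded "
                "from both tables", site.id_a, site.id_b,
            )
    if n_mixed:
        logger.info("%d mixed site pair(s) excluded", n_mixed)
    return sorted(
        reports, key=lambda r: (-r.peak_height, r.protein_id, r.subsequence)
    )
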