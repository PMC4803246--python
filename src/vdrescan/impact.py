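"""Variant impact on the best motif hit at a locus.

For each variant the wild-type and mutant alleles are rescanned around
the variant locus (unthresholded), the best-scoring hit overlapping the
locus is selected on each allele, and the percent change of that best
score is reported. A variant is classified as "disrupts" when the best
overlapping score drops, "creates/duplicates" when the mutant allele
carries strictly more hits at or above the working threshold over the
locus than the wild type (a duplication that copies a whole element),
and "none" when no thresholded hit overlaps the locus in either allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genemodel import (
    CVariant,
    GeneModel,
    apply_variant,
    c_to_contig,
    extract_region,
    variant_length_change,
)
from .motif import MotifHit, Pwm, relative_score, scan

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImpactResult:
    """Outcome of rescoring one variant against the motif model.

    ``pct_change`` is on the raw log-odds scale, positive = reduction of
    the best overlapping score; ``pct_change_relative`` is the same
    quantity on the 0-100% min-max scale (the two are reported side by
    side because published score reductions do not always say which
    scale they used). ``pct_change`` is None when the wild-type best raw
    score is not positive (a sign-flipping denominator is meaningless).
    """

    variant: CVariant
    region_name: str
    locus: tuple[int, int]
    wt_best: MotifHit | None
    mut_best: MotifHit | None
    pct_change: float | None
    pct_change_relative: float | None
    category: str
    wt_hits_at_threshold: int = 0
    mut_hits_at_threshold: int = 0


def _overlaps(hit: MotifHit, locus: tuple[int, int]) -> bool:
    return hit.start < locus[1] and hit.end > locus[0]


def best_hit_over_locus(
    hits: Iterable[MotifHit], locus: tuple[int, int]
) -> MotifHit | None:
    """Best-scoring hit whose window overlaps ``locus`` (0-based half-open).

    Ties break toward the smaller start, then the forward strand.
    """
    if locus[0] >= locus[1]:
        raise ValueError(f"empty locus {locus}")
    best: MotifHit | None = None
    for h in hits:
        if not _overlaps(h, locus):
            continue
        if best is None or (h.raw_score, -h.start, h.strand) > (
            best.raw_score, -best.start, best.strand
        ):
            best = h
    return best


def _shifted(hits: list[MotifHit], offset: int) -> list[MotifHit]:
    return [
        MotifHit(
            sequence_id=h.sequence_id,
            start=h.start + offset,
            strand=h.strand,
            raw_score=h.raw_score,
            relative_score=h.relative_score,
            site=h.site,
        )
        for h in hits
    ]


def assess_variant(
    pwm: Pwm,
    reference: str,
    model: GeneModel,
    v: CVariant,
    window_pad: int | None = None,
    threshold: float = 70.0,
    region_name: str = "",
) -> ImpactResult:
    """Score the wild-type and mutant alleles around a variant.

    Both alleles are scanned unthresholded over a window extending
    ``window_pad`` bases beyond the variant locus (default: motif length
    - 1 plus the variant's length change, the smallest pad whose result
    is invariant to further enlargement). For insertions/duplications the
    mutant locus is widened by the inserted length so shifted copies of a
    site still count as overlapping.
    """
    L = pwm.length
    locus = c_to_contig(model, v)
    delta = variant_length_change(v)
    if window_pad is None:
        window_pad = L - 1 + (locus[1] - locus[0]) + abs(delta)
    if window_pad < L - 1:
        raise ValueError(f"window_pad must be >= motif length - 1 ({L - 1})")

    mutant = apply_variant(reference, model, v)
    if delta >= 0:
        mut_locus = (locus[0], locus[1] + delta)
    else:
        mut_locus = (locus[0], max(locus[0] + 1, locus[1] + delta))

    wt_hits = _window_scan(pwm, reference, locus, window_pad)
    mut_hits = _window_scan(pwm, mutant, mut_locus, window_pad)

    wt_best = best_hit_over_locus(wt_hits, locus)
    mut_best = best_hit_over_locus(mut_hits, mut_locus)
    wt_n = sum(
        1 for h in wt_hits if _overlaps(h, locus) and h.relative_score >= threshold
    )
    mut_n = sum(
        1 for h in mut_hits if _overlaps(h, mut_locus) and h.relative_score >= threshold
    )

    if wt_n == 0 and mut_n == 0:
        category = "none"
    elif mut_n > wt_n:
        category = "creates/duplicates"
    elif wt_best is not None and (
        mut_best is None or mut_best.raw_score < wt_best.raw_score
    ):
        category = "disrupts"
    else:
        category = "none"

    pct = pct_rel = None
    if category == "none" and wt_n == 0 and mut_n == 0:
        pct = pct_rel = 0.0
    elif wt_best is not None:
        mut_raw = mut_best.raw_score if mut_best is not None else pwm.min_score
        if wt_best.raw_score > 0:
            pct = 100.0 * (wt_best.raw_score - mut_raw) / wt_best.raw_score
        else:
            logger.info(
                "%s: wild-type best raw score %.3f <= 0; raw-scale percent "
                "change undefined", v.raw_text, wt_best.raw_score,
            )
        wt_rel = wt_best.relative_score
        mut_rel = relative_score(pwm, mut_raw)
        if wt_rel > 0:
            pct_rel = 100.0 * (wt_rel - mut_rel) / wt_rel

    return ImpactResult(
        variant=v,
        region_name=region_name or _region_of(model, locus),
        locus=locus,
        wt_best=wt_best,
        mut_best=mut_best,
        pct_change=pct,
        pct_change_relative=pct_rel,
        category=category,
        wt_hits_at_threshold=wt_n,
        mut_hits_at_threshold=mut_n,
    )


def _window_scan(
    pwm: Pwm, sequence: str, locus: tuple[int, int], pad: int
) -> list[MotifHit]:
    a = max(0, locus[0] - pad)
    b = min(len(sequence), locus[1] + pad)
    return _shifted(scan(pwm, sequence[a:b], threshold=0.0), a)


def _region_of(model: GeneModel, locus: tuple[int, int]) -> str:
    pos = locus[0]
    if pos < model.translation_start:
        return "promoter"
    for i in range(1, model.n_exons):
        ia, ib = model.intron(i)
        if ia <= pos < ib:
            return f"intron{i}"
    for i in range(1, model.n_exons + 1):
        ea, eb = model.exon(i)
        if ea <= pos < eb:
            return f"exon{i}"
    return "intergenic"


@dataclass
class StudyTables:
    """Joint output of a region scan + variant impact study."""

    inventory: pd.DataFrame
    impacts: pd.DataFrame
    results: list[ImpactResult] = field(default_factory=list)


DEFAULT_REGIONS: tuple = (("promoter", 1500), ("intron", 1), ("intron", 2))


def study_report(
    pwm: Pwm,
    reference: str,
    model: GeneModel,
    variants: Sequence[CVariant],
    regions: Sequence[tuple] | None = None,
    threshold: float = 70.0,
    window_pad: int | None = None,
) -> StudyTables:
    """Scan the study regions for motif hits and assess every variant.

    The inventory lists, per region, every hit at or above ``threshold``
    in deterministic (region, start) order with contig coordinates; the
    impact table has one row per variant.
    """
    if regions is None:
        regions = [("promoter", min(1500, model.translation_start))] + [
            ("intron", i) for i in range(1, model.n_exons)
        ]
    inv_rows = []
    for region in regions:
        name = region[0] if region[0] != "intron" and region[0] != "exon" else (
            f"{region[0]}{region[1]}"
        )
        seq, (a, _b) = extract_region(model, reference, region)
        for h in scan(pwm, seq, threshold=threshold, sequence_id=model.contig_id):
            inv_rows.append(
                {
                    "region": name,
                    "start": h.start + a,
                    "end": h.end + a,
                    "strand": h.strand,
                    "site": h.site,
                    "raw_score": h.raw_score,
                    "relative_score": h.relative_score,
                }
            )
    inventory = pd.DataFrame(
        inv_rows,
        columns=["region", "start", "end", "strand", "site", "raw_score",
                 "relative_score"],
    ).sort_values(["region", "start"], kind="stable").reset_index(drop=True)

    results = []
    imp_rows = []
    for v in variants:
        res = assess_variant(
            pwm, reference, model, v, window_pad=window_pad, threshold=threshold
        )
        results.append(res)
        imp_rows.append(
            {
                "variant": v.raw_text,
                "region": res.region_name,
                "locus_start": res.locus[0],
                "locus_end": res.locus[1],
                "category": res.category,
                "wt_best_raw": res.wt_best.raw_score if res.wt_best else float("nan"),
                "mut_best_raw": res.mut_best.raw_score if res.mut_best else float("nan"),
                "pct_change_raw": res.pct_change,
                "pct_change_relative": res.pct_change_relative,
                "wt_hits_at_threshold": res.wt_hits_at_threshold,
                "mut_hits_at_threshold": res.mut_hits_at_threshold,
            }
        )
    impacts = pd.DataFrame(
        imp_rows,
        columns=["variant", "region", "locus_start", "locus_end", "category",
                 "wt_best_raw", "mut_best_raw", "pct_change_raw",
                 "pct_change_relative", "wt_hits_at_threshold",
                 "mut_hits_at_threshold"],
    )
    return StudyTables(inventory=inventory, impacts=impacts, results=results)
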