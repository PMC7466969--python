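"""Three-stage screen for bacterially derived horizontally transferred genes.

Stage 1 (taxonomy): a gene is a candidate iff, at the e-value cutoff, it has
no passing fungal hit, no passing hit to any other non-bacterial lineage,
and at least one passing bacterial hit.
Stage 2 (coverage): candidates whose mean read depth deviates from the
harboring scaffold's per-base mean by >= ``z_threshold`` scaffold standard
deviations are removed (mis-assembly / contamination signal).
Stage 3 (context): candidates with no fungal-call gene anywhere upstream or
downstream on their scaffold are removed (whole-scaffold contaminants).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GeneModel, HitRecord

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-10
DEFAULT_Z_THRESHOLD = 2.0


@dataclass
class BestHitCall:
    """Per-gene homology verdict: fungal, bacterial, other, or none."""

    gene_id: str
    call: str
    best_hit: HitRecord | None
    top_taxa: tuple[str, ...]  # up to 10 taxonomy groups, ascending e-value


@dataclass
class HgtCandidate:
    gene_id: str
    donor_group: str
    z: float
    passed_coverage: bool
    passed_context: bool

    @property
    def in_final_set(self) -> bool:
        return self.passed_coverage and self.passed_context


@dataclass
class ScreenResult:
    """Everything the screen computed, plus the stage funnel counts."""

    calls: dict[str, BestHitCall]
    candidates: list[HgtCandidate]
    final_set: set[str]
    funnel: dict[str, int]


def _hit_order(h: HitRecord) -> tuple[float, float]:
    # min e-value first; ties broken by max bitscore, then input order (stable sort)
    return (h.evalue, -h.bitscore)


def classify_best_hits(
    hits: Iterable[HitRecord],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    all_gene_ids: Iterable[str] | None = None,
) -> dict[str, BestHitCall]:
    """Classify each gene from its homology hits.

    Hits above the e-value cutoff are discarded.  A single passing fungal
    hit makes the call "fungal"; failing that, any passing hit outside
    bacteria makes it "other" (candidacy requires hits to bacteria only);
    otherwise "bacterial" if any bacterial hit passes, else "none".
    ``all_gene_ids``, if given, adds explicit "none" calls for genes with no
    hits at all.
    """
    by_gene: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_gene.setdefault(h.query_id, []).append(h)
    calls: dict[str, BestHitCall] = {}
    for gene_id, gene_hits in by_gene.items():
        passing = sorted(
            (h for h in gene_hits if h.evalue <= evalue_cutoff), key=_hit_order
        )
        top_taxa = tuple(h.taxonomy_group for h in passing[:10])
        kingdoms = {h.superkingdom for h in passing}
        if not passing:
            call, best = "none", None
        elif "fungi" in kingdoms:
            call = "fungal"
            best = min((h for h in passing if h.superkingdom == "fungi"), key=_hit_order)
        elif kingdoms - {"bacteria"}:
            call = "other"
            best = passing[0]
        else:
            call, best = "bacterial", passing[0]
        calls[gene_id] = BestHitCall(
            gene_id=gene_id, call=call, best_hit=best, top_taxa=top_taxa
        )
    if all_gene_ids is not None:
        for gid in all_gene_ids:
            if gid not in calls:
                calls[gid] = BestHitCall(gene_id=gid, call="none", best_hit=None, top_taxa=())
    return calls


def call_hgt_candidates(calls: Mapping[str, BestHitCall]) -> set[str]:
    """Genes whose only passing hits are bacterial."""
    return {gid for gid, c in calls.items() if c.call == "bacterial"}


def coverage_zscore(
    track: CoverageTrack, gene: GeneModel, ddof: int = 0
) -> float:
    """Standardized deviation of a gene's mean depth from its scaffold's.

    z = (mean depth over the gene span - scaffold per-base mean) / scaffold
    per-base SD.  The scaffold statistics include the gene's own bases, and
    the SD is the population SD by default (``ddof=0``).  Uniform scaffold
    coverage (SD 0) yields z = 0 with a warning: it cannot indicate deviation.
    """
    if gene.scaffold_id != track.scaffold_id:
        raise ValueError(
            f"gene {gene.gene_id} is on {gene.scaffold_id}, track is {track.scaffold_id}"
        )
    depth = track.depth
    s, e = gene.span
    if e > len(depth):
        raise ValueError(f"gene {gene.gene_id} span extends beyond coverage track")
    scaffold_mean = float(depth.mean())
    scaffold_sd = float(depth.std(ddof=ddof))
    gene_mean = float(depth[s:e].mean())
    if scaffold_sd == 0.0:
        logger.warning(
            "scaffold %s has uniform coverage; z for %s set to 0",
            track.scaffold_id,
            gene.gene_id,
        )
        return 0.0
    return (gene_mean - scaffold_mean) / scaffold_sd


def apply_coverage_filter(
    candidates: Iterable[str],
    zscores: Mapping[str, float],
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> set[str]:
    """Retain candidates with |z| strictly below the threshold."""
    retained = set()
    for gid in candidates:
        if gid not in zscores:
            raise KeyError(f"no coverage z-score for candidate gene {gid}")
        if abs(zscores[gid]) < threshold:
            retained.add(gid)
    return retained


def apply_context_filter(
    candidates: Iterable[str],
    genes: Sequence[GeneModel],
    calls: Mapping[str, BestHitCall],
) -> set[str]:
    """Retain candidates with >=1 fungal-call gene up- or downstream on the scaffold."""
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    for glist in by_scaffold.values():
        glist.sort(key=lambda g: g.span)
    pos = {g.gene_id: (g.scaffold_id, g.span[0]) for g in genes}
    retained = set()
    for gid in candidates:
        scaf, start = pos[gid]
        for other in by_scaffold[scaf]:
            if other.gene_id == gid:
                continue
            call = calls.get(other.gene_id)
            if call is not None and call.call == "fungal":
                retained.add(gid)
                break
    return retained


def summarize_donor_taxa(candidates: Iterable[HgtCandidate]) -> pd.DataFrame:
    """Counts and proportions of donor taxonomy groups over the final set."""
    counts = Counter(c.donor_group for c in candidates if c.in_final_set)
    rows = [
        {"taxonomy_group": grp, "count": n, "proportion": n / sum(counts.values())}
        for grp, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["taxonomy_group", "count", "proportion"])


def screen(
    genes: Sequence[GeneModel],
    hits: Iterable[HitRecord],
    tracks: Iterable[CoverageTrack],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    sd_ddof: int = 0,
) -> ScreenResult:
    """Run the full three-stage screen and record the stage funnel."""
    track_by_scaffold = {t.scaffold_id: t for t in tracks}
    calls = classify_best_hits(
        hits, evalue_cutoff=evalue_cutoff, all_gene_ids=[g.gene_id for g in genes]
    )
    candidate_ids = call_hgt_candidates(calls)
    gene_by_id = {g.gene_id: g for g in genes}
    zscores = {}
    for gid in candidate_ids:
        g = gene_by_id[gid]
        if g.scaffold_id not in track_by_scaffold:
            raise KeyError(f"no coverage track for scaffold {g.scaffold_id}")
        zscores[gid] = coverage_zscore(track_by_scaffold[g.scaffold_id], g, ddof=sd_ddof)
    coverage_pass = apply_coverage_filter(candidate_ids, zscores, threshold=z_threshold)
    context_pass = apply_context_filter(candidate_ids, genes, calls)
    final = coverage_pass & context_pass
    candidates = [
        HgtCandidate(
            gene_id=gid,
            donor_group=(
                calls[gid].best_hit.taxonomy_group if calls[gid].best_hit else "unknown"
            ),
            z=zscores[gid],
            passed_coverage=gid in coverage_pass,
            passed_context=gid in context_pass,
        )
        for gid in sorted(candidate_ids)
    ]
    funnel = {
        "genes": len(genes),
        "bacterial_only": len(candidate_ids),
        "coverage_pass": len(coverage_pass),
        "context_pass": len(context_pass),
        "final": len(final),
    }
    logger.info(
        "screen funnel: %d genes -> %d bacterial-only -> %d coverage-pass -> %d final",
        funnel["genes"], funnel["bacterial_only"], funnel["coverage_pass"], funnel["final"],
    )
    return ScreenResult(calls=calls, candidates=candidates, final_set=final, funnel=funnel)


def candidates_to_frame(candidates: Iterable[HgtCandidate]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "donor_group": c.donor_group,
            "z": c.z,
            "passed_coverage": c.passed_coverage,
            "passed_context": c.passed_context,
            "final": c.in_final_set,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "donor_group", "z", "passed_coverage", "passed_context", "final"],
    )
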