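"""Secondary-metabolism gene census and its cross-tabulations.

Core-gene ledgers merge antiSMASH- and SMURF-style predictions; counts are
pooled per genome into the presentation classes (NRPS with NRPS-like, PKS
with PKS-like), cross-tabulated against a horizontally transferred gene
set, placed into named phylogenetic clades by MRCA containment, and
summarized for expression (TPM) and domain content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import DomainHit, Interval

logger = logging.getLogger(__name__)

SM_CLASSES = ("NRPS", "NRPS-like", "PKS", "PKS-like", "NRPS-PKS hybrid", "TC", "DMAT")

#: Strings seen in prediction tables, mapped onto the closed vocabulary.
_CLASS_ALIASES = {
    "nrps": "NRPS",
    "nrps-like": "NRPS-like",
    "nrps_like": "NRPS-like",
    "pks": "PKS",
    "pks-like": "PKS-like",
    "pks_like": "PKS-like",
    "nrps-pks hybrid": "NRPS-PKS hybrid",
    "nrps-pks": "NRPS-PKS hybrid",
    "hybrid": "NRPS-PKS hybrid",
    "tc": "TC",
    "terpene": "TC",
    "terpene cyclase": "TC",
    "dmat": "DMAT",
}

#: Pooled presentation classes -> fine classes.
POOLED_CLASSES = {
    "NRPS/NRPS-like": ("NRPS", "NRPS-like"),
    "PKS/PKS-like": ("PKS", "PKS-like"),
    "NRPS-PKS hybrids": ("NRPS-PKS hybrid",),
    "TC": ("TC",),
}

PKS_DOMAIN_SET = ("KS", "AT", "KR", "DH", "PP")


def normalize_sm_class(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _CLASS_ALIASES:
        raise ValueError(
            f"unknown SM class {label!r}; allowed: {', '.join(SM_CLASSES)}"
        )
    return _CLASS_ALIASES[key]


@dataclass
class SmCoreGene:
    """One secondary-metabolism core gene in the census ledger."""

    gene_id: str
    genome_id: str
    sm_class: str
    cluster_id: str | None = None
    source: str = "antismash"  # antismash | smurf | both
    domains: list[tuple[str, Interval]] = field(default_factory=list)
    clade: str | None = None
    tpm: float | None = None
    z: float | None = None
    donor: str | None = None

    def __post_init__(self) -> None:
        self.sm_class = normalize_sm_class(self.sm_class)


@dataclass(frozen=True)
class CladeDefinition:
    """A named reference clade: the query is placed by MRCA containment."""

    clade_name: str
    reference_tips: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.reference_tips) < 2:
            raise ValueError(f"clade {self.clade_name} needs >= 2 reference tips")


def merge_sm_predictions(
    antismash: pd.DataFrame, smurf: pd.DataFrame
) -> list[SmCoreGene]:
    """Union of two class-labeled prediction tables keyed by gene_id.

    Class conflicts resolve in favor of the antiSMASH label and are logged;
    the record's ``source`` says where each gene was predicted.
    Tables need columns gene_id, genome_id, sm_class (cluster_id optional).
    """

    def index(df: pd.DataFrame) -> dict[str, dict]:
        out = {}
        for row in df.to_dict("records"):
            row["sm_class"] = normalize_sm_class(row["sm_class"])
            out[str(row["gene_id"])] = row
        return out

    a, s = index(antismash), index(smurf)
    merged: list[SmCoreGene] = []
    for gid in sorted(set(a) | set(s)):
        if gid in a and gid in s:
            if a[gid]["sm_class"] != s[gid]["sm_class"]:
                logger.warning(
                    "class conflict for %s: antismash=%s smurf=%s (keeping antismash)",
                    gid, a[gid]["sm_class"], s[gid]["sm_class"],
                )
            row, source = a[gid], "both"
        elif gid in a:
            row, source = a[gid], "antismash"
        else:
            row, source = s[gid], "smurf"
        merged.append(
            SmCoreGene(
                gene_id=gid,
                genome_id=str(row["genome_id"]),
                sm_class=row["sm_class"],
                cluster_id=(str(row["cluster_id"]) if row.get("cluster_id") not in (None, "", ".") else None),
                source=source,
            )
        )
    return merged


def tabulate_sm_counts(ledger: Sequence[SmCoreGene]) -> pd.DataFrame:
    """Genome x pooled-class count table with a Total SM column."""
    if not ledger:
        return pd.DataFrame(columns=["Total SM", *POOLED_CLASSES])
    genomes = sorted({g.genome_id for g in ledger})
    rows = []
    for genome in genomes:
        classes = [g.sm_class for g in ledger if g.genome_id == genome]
        row = {"genome_id": genome, "Total SM": len(classes)}
        for pooled, fine in POOLED_CLASSES.items():
            row[pooled] = sum(c in fine for c in classes)
        n_dmat = sum(c == "DMAT" for c in classes)
        if n_dmat:
            row["DMAT"] = n_dmat
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome_id")


def crosstab_hgt(
    ledger: Sequence[SmCoreGene], final_hgt_set: set[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Per genome and pooled class: transferred count, class total and fraction.

    Returns a frame with MultiIndex columns (class, {hgt, total, percent})
    plus the list of transferred genes absent from the ledger (non-SM HGT),
    which are logged rather than raised.
    """
    ledger_ids = {g.gene_id for g in ledger}
    non_sm = sorted(final_hgt_set - ledger_ids)
    if non_sm:
        logger.info("%d transferred genes are not SM core genes", len(non_sm))
    genomes = sorted({g.genome_id for g in ledger})
    cols = list(POOLED_CLASSES) + ["Total SM"]
    data = {}
    for genome in genomes:
        sub = [g for g in ledger if g.genome_id == genome]
        row = {}
        for pooled, fine in list(POOLED_CLASSES.items()) + [("Total SM", SM_CLASSES)]:
            members = [g for g in sub if g.sm_class in fine]
            hgt = sum(g.gene_id in final_hgt_set for g in members)
            total = len(members)
            pct = 100.0 * hgt / total if total else 0.0
            row[(pooled, "hgt")] = hgt
            row[(pooled, "total")] = total
            row[(pooled, "percent")] = pct
        data[genome] = row
    frame = pd.DataFrame(data).T
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    frame = frame[[c for c in cols]]
    return frame, non_sm


def format_crosstab(crosstab: pd.DataFrame) -> pd.DataFrame:
    """Render crosstab cells as "n/m (p%)" strings (percent recomputed, rounded)."""
    out = {}
    for pooled in crosstab.columns.levels[0]:
        col = []
        for genome in crosstab.index:
            hgt = int(crosstab.loc[genome, (pooled, "hgt")])
            total = int(crosstab.loc[genome, (pooled, "total")])
            pct = round(100.0 * hgt / total) if total else 0
            col.append(f"{hgt}/{total} ({pct}%)")
        out[pooled] = col
    return pd.DataFrame(out, index=crosstab.index)


# ---------------------------------------------------------------------------
# clade assignment


def _reroot_at_outgroup(tree: dendropy.Tree, outgroup_tips: Iterable[str]) -> None:
    taxa = [tree.taxon_namespace.get_taxon(t) for t in outgroup_tips]
    missing = [t for t, tx in zip(outgroup_tips, taxa) if tx is None]
    if missing:
        raise ValueError(f"outgroup tips missing from tree: {', '.join(missing)}")
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(taxa[0].label)
    else:
        node = tree.mrca(taxa=taxa)
    if node is not tree.seed_node:
        tree.reroot_at_edge(node.edge, update_bipartitions=True)


def assign_clades(
    tree: dendropy.Tree,
    clade_definitions: Sequence[CladeDefinition],
    query_tips: Iterable[str],
    outgroup_tips: Iterable[str] | None = None,
) -> dict[str, str]:
    """Place each query tip into the smallest named clade containing it.

    A query belongs to clade C when it descends from the MRCA of C's
    reference tips (on the tree rooted by the supplied outgroup).  Queries
    under no named MRCA are "unassigned".  A reference tip absent from the
    tree is an error naming the tip.
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    if outgroup_tips:
        _reroot_at_outgroup(tree, list(outgroup_tips))
    label_to_leaf = {}
    for leaf in tree.leaf_node_iter():
        label_to_leaf[leaf.taxon.label] = leaf
    clade_nodes: list[tuple[str, set[str]]] = []
    seen_refs: set[str] = set()
    for cd in clade_definitions:
        if seen_refs & cd.reference_tips:
            raise ValueError(f"clade {cd.clade_name}: reference tips overlap another clade")
        seen_refs |= cd.reference_tips
        for tip in sorted(cd.reference_tips):
            if tip not in label_to_leaf:
                raise ValueError(f"reference tip {tip!r} missing from tree")
        mrca = tree.mrca(taxa=[label_to_leaf[t].taxon for t in sorted(cd.reference_tips)])
        leafset = {lf.taxon.label for lf in mrca.leaf_iter()}
        clade_nodes.append((cd.clade_name, leafset))
    assignments: dict[str, str] = {}
    for q in query_tips:
        if q not in label_to_leaf:
            raise ValueError(f"query tip {q!r} missing from tree")
        best = None
        for name, leafset in clade_nodes:
            if q in leafset and (best is None or len(leafset) < best[1]):
                best = (name, len(leafset))
        assignments[q] = best[0] if best else "unassigned"
    return assignments


def clade_abundance_matrix(
    assignments: Mapping[str, str], genome_of: Mapping[str, str]
) -> pd.DataFrame:
    """Genome x clade integer counts; row sums equal per-genome query counts."""
    if not assignments:
        return pd.DataFrame(dtype=int)
    rows = [
        {"genome_id": genome_of[q], "clade": c} for q, c in assignments.items()
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["genome_id", "clade"]).size().unstack(fill_value=0).astype(int)
    )


# ---------------------------------------------------------------------------
# domain summaries


def domain_architecture(
    protein_length: int, domains: Sequence[DomainHit]
) -> list[dict]:
    """Fraction-of-length layout of a protein's domains, order preserved.

    Overlapping envelopes keep the higher-scoring hit (logged).
    """
    if protein_length <= 0:
        raise ValueError("protein length must be positive")
    kept: list[DomainHit] = []
    for hit in sorted(domains, key=lambda h: (-h.score, h.interval)):
        s, e = hit.interval
        if s < 0 or e > protein_length:
            raise ValueError(
                f"domain {hit.domain_name} interval {hit.interval} outside protein"
            )
        if any(s < k.interval[1] and k.interval[0] < e for k in kept):
            logger.warning(
                "dropping overlapping lower-score domain %s at %s", hit.domain_name, hit.interval
            )
            continue
        kept.append(hit)
    kept.sort(key=lambda h: h.interval)
    return [
        {
            "domain_name": h.domain_name,
            "start_frac": h.interval[0] / protein_length,
            "end_frac": h.interval[1] / protein_length,
            "score": h.score,
        }
        for h in kept
    ]


def domain_presence_matrix(
    gene_ids: Sequence[str],
    domain_hits: Sequence[DomainHit],
    domain_set: Sequence[str] = PKS_DOMAIN_SET,
) -> pd.DataFrame:
    """Gene x domain boolean matrix: presence = >=1 hit for that domain."""
    present: dict[str, set[str]] = {g: set() for g in gene_ids}
    for h in domain_hits:
        if h.query_id in present and h.domain_name in domain_set:
            present[h.query_id].add(h.domain_name)
    return pd.DataFrame(
        {d: [d in present[g] for g in gene_ids] for d in domain_set},
        index=list(gene_ids),
    )


# ---------------------------------------------------------------------------
# expression


def tpm_normalize(counts, lengths) -> pd.Series:
    """Transcripts per million from raw counts and effective lengths.

    rate_g = count_g / length_g; TPM_g = 1e6 * rate_g / sum(rates).
    """
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        raise ValueError("all counts are zero; TPM undefined")
    return 1e6 * rates / total


def expression_report(
    tpm: pd.Series,
    ledger: Sequence[SmCoreGene],
    housekeeping_ids: Sequence[str],
) -> pd.DataFrame:
    """Per SM core gene: TPM, class, rank among all genes, expression flag.

    The flag marks SM genes whose TPM reaches the minimum TPM of the
    housekeeping reference set; housekeeping IDs absent from ``tpm`` are
    warned about and excluded.
    """
    tpm = pd.Series(tpm, dtype=float)
    present_hk = [h for h in housekeeping_ids if h in tpm.index]
    for h in housekeeping_ids:
        if h not in tpm.index:
            logger.warning("housekeeping gene %s absent from TPM table; excluded", h)
    if not present_hk:
        raise ValueError("no housekeeping gene present in the TPM table")
    hk_min = float(tpm[present_hk].min())
    ranks = tpm.rank(ascending=False, method="min").astype(int)
    rows = []
    for g in ledger:
        if g.gene_id not in tpm.index:
            logger.warning("SM gene %s absent from TPM table; skipped", g.gene_id)
            continue
        val = float(tpm[g.gene_id])
        rows.append(
            {
                "gene_id": g.gene_id,
                "sm_class": g.sm_class,
                "tpm": val,
                "rank": int(ranks[g.gene_id]),
                "expressed_at_housekeeping_level": bool(val >= hk_min and val > 0),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "sm_class", "tpm", "rank", "expressed_at_housekeeping_level"]
    )
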