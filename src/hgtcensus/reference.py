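"""Published census tables for the three Basidiobolus isolates.

Three small tab-separated tables ship with the package:

* ``table1_sm_core_counts.tsv`` — per-isolate counts of predicted SM core
  genes by pooled class (NRPS with NRPS-like, PKS with PKS-like, hybrids,
  terpene cyclases).
* ``table2_hgt_sm_counts.tsv`` — the same layout with "n/m (p%)" cells for
  the subset with horizontal-transfer evidence, as printed.  Two printed
  cells are internally inconsistent; the counts are treated as
  authoritative and percentages are always recomputed downstream.
* ``table3_hgt_sm_genes.tsv`` — the per-gene roster of SM core genes with
  transfer evidence: coverage z-score, SM class and best-hit donor taxon.

``build_census_ledger`` turns these into a per-gene ledger: the transferred
genes come from table 3 verbatim, and each genome is padded with synthetic
filler records (no published gene IDs exist for the non-transferred genes)
so pooled class totals match table 1.
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

from .sm_census import SmCoreGene, normalize_sm_class

ISOLATES = (
    "B. meristosporus CBS 931.73",
    "B. meristosporus B9252",
    "B. heterosporus B8920",
)

_POOL_COLUMNS = {
    "nrps_pool": "NRPS/NRPS-like",
    "pks_pool": "PKS/PKS-like",
    "hybrids": "NRPS-PKS hybrids",
    "tc": "TC",
}

#: Fine class used for the synthetic filler records of each pool.
_FILLER_CLASS = {
    "nrps_pool": "NRPS-like",
    "pks_pool": "PKS-like",
    "hybrids": "NRPS-PKS hybrid",
    "tc": "TC",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("hgtcensus").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_sm_core_counts() -> pd.DataFrame:
    """Per-isolate pooled SM core-gene counts (table 1), as integers."""
    df = _read("table1_sm_core_counts.tsv").set_index("isolate")
    return df.astype(int)


def _parse_fraction(cell: str) -> tuple[int, int]:
    m = re.match(r"(\d+)/(\d+)", cell.strip())
    if not m:
        raise ValueError(f"cannot parse fraction cell {cell!r}")
    return int(m.group(1)), int(m.group(2))


def load_hgt_sm_counts() -> pd.DataFrame:
    """Transferred/total counts per isolate and pool (table 2), percentages dropped.

    Returns a frame with MultiIndex columns (pool, {hgt, total}).
    """
    raw = _read("table2_hgt_sm_counts.tsv").set_index("isolate")
    data = {}
    for col in raw.columns:
        pool = _POOL_COLUMNS.get(col, "Total SM")
        hgt, total = zip(*(_parse_fraction(c) for c in raw[col]))
        data[(pool, "hgt")] = hgt
        data[(pool, "total")] = total
    return pd.DataFrame(data, index=raw.index)


def load_hgt_sm_genes() -> pd.DataFrame:
    """Per-gene roster of SM core genes with transfer evidence (table 3)."""
    df = _read("table3_hgt_sm_genes.tsv")
    df["z"] = df["z"].astype(float)
    return df


def hgt_gene_ids() -> set[str]:
    return set(load_hgt_sm_genes()["gene_id"])


def build_census_ledger() -> list[SmCoreGene]:
    """Per-gene ledger combining the transferred roster with synthetic filler.

    Pooled per-genome class totals match table 1 exactly; only the
    transferred records carry published gene IDs, z-scores and donor taxa.
    """
    table1 = load_sm_core_counts()
    roster = load_hgt_sm_genes()
    ledger: list[SmCoreGene] = []
    for isolate in table1.index:
        sub = roster[roster["isolate"] == isolate]
        for row in sub.itertuples(index=False):
            ledger.append(
                SmCoreGene(
                    gene_id=row.gene_id,
                    genome_id=isolate,
                    sm_class=row.sm_class,
                    z=row.z,
                    donor=row.donor_taxonomy,
                )
            )
        pool_of = {
            "NRPS": "nrps_pool", "NRPS-like": "nrps_pool",
            "PKS": "pks_pool", "PKS-like": "pks_pool",
            "NRPS-PKS hybrid": "hybrids", "TC": "tc",
        }
        have = {"nrps_pool": 0, "pks_pool": 0, "hybrids": 0, "tc": 0}
        for row in sub.itertuples(index=False):
            have[pool_of[normalize_sm_class(row.sm_class)]] += 1
        short = isolate.split()[-1]
        for pool, n_have in have.items():
            deficit = int(table1.loc[isolate, pool]) - n_have
            if deficit < 0:
                # table 2/3 inconsistency: the roster already exceeds the pool
                # total; keep the roster (counts authoritative), add no filler
                deficit = 0
            for i in range(deficit):
                ledger.append(
                    SmCoreGene(
                        gene_id=f"{short}_filler_{pool}_{i:02d}",
                        genome_id=isolate,
                        sm_class=_FILLER_CLASS[pool],
                    )
                )
    return ledger
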