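"""Orchestration: simulate -> screen -> stats -> census as one seeded run.

Each stage writes plain TSV outputs into the run directory and the run
manifest records the seed, the configuration snapshot, SHA-256 digests of
every file and the screen funnel counts, so a rerun with the same manifest
reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition_stats as cs
from . import io_formats, sm_census, synthetic_data
from .hgt_screen import ScreenResult, candidates_to_frame, screen, summarize_donor_taxa

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_screen(
    gff: Path,
    fasta: Path,
    hits: Path,
    taxmap: Path,
    depth: Path,
    outdir: Path,
    evalue_cutoff: float = 1e-10,
    z_threshold: float = 2.0,
) -> ScreenResult:
    """Run the three-stage screen from files and write its output tables."""
    outdir.mkdir(parents=True, exist_ok=True)
    genes = io_formats.parse_gff3(gff)
    scaffolds = io_formats.read_fasta(fasta)
    lengths = {name: len(seq) for name, seq in scaffolds.items()}
    hit_records = io_formats.parse_blast6(hits, io_formats.read_taxonomy_map(taxmap))
    tracks = io_formats.parse_depth(depth, scaffold_lengths=lengths)
    result = screen(
        genes, hit_records, tracks, evalue_cutoff=evalue_cutoff, z_threshold=z_threshold
    )
    candidates_to_frame(result.candidates).to_csv(
        outdir / "candidates.tsv", sep="\t", index=False
    )
    summarize_donor_taxa(result.candidates).to_csv(
        outdir / "donors.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"gene_id": gid, "call": c.call, "top_taxa": ";".join(c.top_taxa) or "."}
            for gid, c in sorted(result.calls.items())
        ]
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    return result


def stage_stats(
    genes: list[io_formats.GeneModel],
    scaffolds: dict[str, str],
    result: ScreenResult,
    outdir: Path,
    permutation_seed: int = 0,
) -> pd.DataFrame:
    """Composition battery on the screened genome; writes stats.tsv and PCA scores."""
    outdir.mkdir(parents=True, exist_ok=True)
    calls = {gid: c.call for gid, c in result.calls.items()}
    groups_of = cs.composition_groups(genes, calls, result.final_set)
    comps = []
    for g in genes:
        grp = groups_of.get(g.gene_id)
        if grp is None:
            continue
        cds = io_formats.extract_cds(g, scaffolds[g.scaffold_id])
        comps.append(cs.gene_composition(g, cds, grp))
    order = ["hgt", "neighbor_fungal", "all_fungal"]
    present = [o for o in order if any(c.group == o for c in comps)]
    rows = []
    if len(present) >= 2 and all(
        sum(c.group == o for c in comps) >= 2 for o in present
    ):
        gc_groups = [[c.gc for c in comps if c.group == o] for o in present]
        res = cs.anova_oneway(gc_groups)
        rows.append({"test": "gc_anova", "statistic": res.statistic, "df": str(res.df), "p": res.p})
        for pair, p in cs.tukey_hsd(gc_groups, names=present).items():
            rows.append({"test": f"gc_tukey:{pair[0]}|{pair[1]}", "statistic": np.nan, "df": ".", "p": p})
        intron_groups = [[c.n_introns for c in comps if c.group == o] for o in present]
        try:
            res = cs.kruskal_wallis(intron_groups)
            rows.append({"test": "introns_kruskal", "statistic": res.statistic, "df": str(res.df), "p": res.p})
        except ValueError:
            logger.warning("intron counts all identical; Kruskal-Wallis undefined")
        norm_groups = [[c.norm_intron_len for c in comps if c.group == o] for o in present]
        try:
            res = cs.kruskal_wallis(norm_groups)
            rows.append({"test": "norm_intron_len_kruskal", "statistic": res.statistic, "df": str(res.df), "p": res.p})
        except ValueError:
            pass
    for feat in ("kmer_vec", "codon_vec") if comps else ():
        mat = np.vstack([getattr(c, feat) for c in comps])
        pca = cs.pca(mat)
        name = "kmer5" if feat == "kmer_vec" else "codon"
        scores = pd.DataFrame(
            pca.scores[:, :2], columns=["PC1", "PC2"],
        )
        scores.insert(0, "gene_id", [c.gene_id for c in comps])
        scores.insert(1, "group", [c.group for c in comps])
        scores.to_csv(outdir / f"pca_{name}_scores.tsv", sep="\t", index=False)
        rows.append(
            {"test": f"pca_{name}_pc1_var", "statistic": pca.variance_fraction[0], "df": ".", "p": np.nan}
        )
        labels = np.array([c.group for c in comps])
        is_hgt = labels == "hgt"
        if 2 <= is_hgt.sum() and 2 <= (~is_hgt).sum():
            perm = cs.permutation_group_separation(
                pca.scores, np.where(is_hgt, "hgt", "fungal"), seed=permutation_seed
            )
            rows.append(
                {"test": f"pca_{name}_separation_perm", "statistic": perm.statistic, "df": ".", "p": perm.p}
            )
    stats = pd.DataFrame(rows, columns=["test", "statistic", "df", "p"])
    stats.to_csv(outdir / "stats.tsv", sep="\t", index=False, na_rep=".")
    return stats


def run_pipeline(
    config: synthetic_data.SimulationConfig,
    outdir: str | Path,
    evalue_cutoff: float = 1e-10,
    z_threshold: float = 2.0,
    sm_fraction: float = 0.15,
) -> dict:
    """Simulate, screen, run the statistics and census; return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = synthetic_data.simulate_genome(config)
    paths = synthetic_data.write_screen_inputs(truth, outdir)
    result = stage_screen(
        paths["gff3"], paths["fasta"], paths["hits"], paths["taxmap"], paths["depth"],
        outdir, evalue_cutoff=evalue_cutoff, z_threshold=z_threshold,
    )
    genes = io_formats.parse_gff3(paths["gff3"])
    scaffolds = io_formats.read_fasta(paths["fasta"])
    stage_stats(genes, scaffolds, result, outdir, permutation_seed=config.seed)

    ledger_df = synthetic_data.emit_sm_ledger(truth, fraction=sm_fraction)
    ledger_df.to_csv(outdir / "sm_ledger.tsv", sep="\t", index=False)
    ledger = [
        sm_census.SmCoreGene(
            gene_id=r.gene_id, genome_id=r.genome_id, sm_class=r.sm_class
        )
        for r in ledger_df.itertuples(index=False)
    ]
    sm_census.tabulate_sm_counts(ledger).to_csv(outdir / "sm_counts.tsv", sep="\t")
    crosstab, _ = sm_census.crosstab_hgt(ledger, result.final_set)
    sm_census.format_crosstab(crosstab).to_csv(outdir / "sm_hgt_crosstab.tsv", sep="\t")

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "parameters": {
            "evalue_cutoff": evalue_cutoff,
            "z_threshold": z_threshold,
            "sm_fraction": sm_fraction,
        },
        "funnel": result.funnel,
        "digests": {
            p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline funnel: %s", result.funnel)
    return manifest
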