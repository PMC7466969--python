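"""Synthetic fungal genome with planted bacterial-origin genes.

The generator emulates the inputs of the screen at the statistical structure
the analysis assumes: a multi-scaffold genome whose genes fall into three
truth classes (fungal, hgt, contaminant), per-base read-depth tracks,
BLAST-tabular homology hits with a subject taxonomy map, and CAS-plate
photographs for the siderophore assay.

Defaults encode the study conditions: fungal CDS GC 0.4865 vs 0.4911 for
transferred genes; 36% of fungal genes intronless (median 2 introns) vs 61%
intronless for transferred genes (median 0); contaminant scaffolds with
deviant coverage.  Every emitter is bit-deterministic under the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from . import io_formats
from .io_formats import CoverageTrack, GeneModel

DONOR_GROUPS = ("Proteobacteria", "Firmicutes", "Actinobacteria", "Bacteroidetes")
DONOR_WEIGHTS = (0.45, 0.20, 0.20, 0.15)

#: Poisson rates of the zero-inflated intron-count model.  The inflation mass
#: is solved from the configured intronless fraction; at the defaults the
#: fungal distribution has P(0)=0.36 and median 2, the transferred one
#: P(0)=0.61 and median 0.
FUNGAL_INTRON_LAMBDA = 3.0
HGT_INTRON_LAMBDA = 1.5

_STOP_CODONS = ("TAA", "TAG", "TGA")
_CODONS = np.array([a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"])
_SENSE = np.array([c not in _STOP_CODONS for c in _CODONS])
_GC_COUNT = np.array([sum(b in "GC" for b in c) for c in _CODONS], dtype=float)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_scaffolds: int = 10
    genes_per_scaffold: int = 20
    hgt_fraction: float = 0.05
    contaminant_scaffold_fraction: float = 0.1
    fungal_gc: float = 0.4865
    hgt_gc: float = 0.4911
    neighbor_gc: float = 0.488
    gc_sd: float = 0.08  # between-gene GC dispersion within a class
    fungal_intronless_fraction: float = 0.36
    hgt_intronless_fraction: float = 0.61
    fungal_intron_median: int = 2
    mean_depth: float = 50.0
    contaminant_depth_multiplier: float = 4.0
    deviant_gene_count: int = 0
    deviant_depth_multiplier: float = 5.0
    noise_fraction: float = 0.0  # fungal genes also given bacterial hits
    composition_separation: float = 0.0  # 0 = non-separable codon regime
    donor_groups: tuple[str, ...] = DONOR_GROUPS
    donor_weights: tuple[float, ...] = DONOR_WEIGHTS
    min_codons: int = 100
    max_codons: int = 500

    def __post_init__(self) -> None:
        for name in (
            "hgt_fraction",
            "contaminant_scaffold_fraction",
            "fungal_gc",
            "hgt_gc",
            "fungal_intronless_fraction",
            "hgt_intronless_fraction",
            "noise_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mean_depth <= 0 or self.contaminant_depth_multiplier <= 0:
            raise ValueError("depth parameters must be positive")
        if abs(sum(self.donor_weights) - 1.0) > 1e-9:
            raise ValueError("donor weights must sum to 1")


@dataclass
class SyntheticTruth:
    """The generated genome plus the planted ground truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    labels: dict[str, str]  # fungal | hgt | contaminant
    donors: dict[str, str]  # hgt/contaminant gene -> taxonomy group
    cds: dict[str, str]
    scaffold_sequences: dict[str, str]
    scaffold_labels: dict[str, str]  # normal | contaminant
    deviant_genes: set[str]

    def gene_ids(self, label: str) -> set[str]:
        return {g for g, lab in self.labels.items() if lab == label}

    @property
    def expected_final_hgt(self) -> set[str]:
        """Planted transferred genes the full screen should retain.

        Contaminant-scaffold genes fail the context filter and planted
        coverage-deviant genes fail the z filter, so the expectation is the
        planted hgt set minus the deviants.
        """
        return self.gene_ids("hgt") - self.deviant_genes

    def mean_gc(self, label: str) -> float:
        from .composition_stats import gc_content

        ids = self.gene_ids(label)
        return float(np.mean([gc_content(self.cds[g]) for g in ids]))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, GFF3 and a truth-label table; return the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "gff3": outdir / "genes.gff3",
            "labels": outdir / "truth_labels.tsv",
        }
        io_formats.write_fasta(self.scaffold_sequences, paths["fasta"])
        io_formats.write_gff3(self.genes, paths["gff3"])
        with open(paths["labels"], "w") as fh:
            fh.write("gene_id\tlabel\tdonor_group\tcoverage_deviant\n")
            for g in self.genes:
                fh.write(
                    f"{g.gene_id}\t{self.labels[g.gene_id]}\t"
                    f"{self.donors.get(g.gene_id, '.')}\t"
                    f"{int(g.gene_id in self.deviant_genes)}\n"
                )
        return paths


# ---------------------------------------------------------------------------
# codon-level sequence model

_CAL_GRID = np.linspace(0.05, 0.95, 181)


def _codon_probs(base_gc: float, tilt: np.ndarray | None = None) -> np.ndarray:
    """Codon probabilities from i.i.d. base frequencies, stops excluded."""
    g = base_gc / 2.0
    a = (1.0 - base_gc) / 2.0
    logp = _GC_COUNT * math.log(g) + (3.0 - _GC_COUNT) * math.log(a)
    p = np.exp(logp)
    p[~_SENSE] = 0.0
    if tilt is not None:
        p = p * np.exp(tilt)
    return p / p.sum()


def _achieved_gc(base_gc: float) -> float:
    p = _codon_probs(base_gc)
    return float((p * _GC_COUNT / 3.0).sum())


_CAL_ACHIEVED = np.array([_achieved_gc(b) for b in _CAL_GRID])


def _base_gc_for_target(target_gc: np.ndarray | float) -> np.ndarray:
    """Invert the stop-exclusion bias so sense codons hit the target GC in expectation."""
    return np.interp(target_gc, _CAL_ACHIEVED, _CAL_GRID)


def _preference_tilt(rng_const_seed: int = 12345) -> np.ndarray:
    """A fixed codon-preference direction used for the separable regime."""
    rng = np.random.default_rng(rng_const_seed)
    tilt = rng.normal(0.0, 1.0, size=64)
    tilt[~_SENSE] = 0.0
    return tilt


_TILT = _preference_tilt()


def sample_cds(
    rng: np.random.Generator,
    n_codons: int,
    target_gc: float,
    separation: float = 0.0,
) -> str:
    """One CDS drawn codon-wise at the given expected GC."""
    base = float(_base_gc_for_target(target_gc))
    tilt = _TILT * separation if separation else None
    probs = _codon_probs(base, tilt)
    idx = rng.choice(64, size=n_codons, p=probs)
    return "".join(_CODONS[idx])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def sample_intron_counts(
    rng: np.random.Generator, n: int, intronless_fraction: float, lam: float
) -> np.ndarray:
    """Zero-inflated Poisson intron counts hitting the configured zero fraction."""
    p0_pois = math.exp(-lam)
    if intronless_fraction < p0_pois:
        raise ValueError(
            f"intronless fraction {intronless_fraction} below Poisson({lam}) zero mass"
        )
    pi = (intronless_fraction - p0_pois) / (1.0 - p0_pois)
    counts = rng.poisson(lam, size=n)
    counts[rng.random(n) < pi] = 0
    return counts


# ---------------------------------------------------------------------------
# genome simulation


def simulate_genome(config: SimulationConfig) -> SyntheticTruth:
    """Build the synthetic genome and its planted truth, deterministically."""
    rng = np.random.default_rng([config.seed, 1])
    n_cont = round(config.contaminant_scaffold_fraction * config.n_scaffolds)
    if config.contaminant_scaffold_fraction > 0 and n_cont == 0:
        raise ValueError("contaminant_scaffold_fraction too small for n_scaffolds")
    if n_cont >= config.n_scaffolds:
        raise ValueError("every scaffold would be contaminant; no fungal class left")
    cont_scaffolds = set(
        rng.choice(config.n_scaffolds, size=n_cont, replace=False).tolist()
    )

    n_normal_genes = (config.n_scaffolds - n_cont) * config.genes_per_scaffold
    n_hgt = round(config.hgt_fraction * n_normal_genes)
    if config.hgt_fraction > 0 and n_hgt == 0:
        raise ValueError("hgt_fraction too small to plant any gene at this size")
    if config.deviant_gene_count > n_hgt:
        raise ValueError("more coverage-deviant genes requested than planted hgt genes")

    # which normal-scaffold gene slots carry transferred genes
    hgt_slots = set(rng.choice(n_normal_genes, size=n_hgt, replace=False).tolist())

    genes: list[GeneModel] = []
    labels: dict[str, str] = {}
    donors: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    scaffold_sequences: dict[str, str] = {}
    scaffold_labels: dict[str, str] = {}
    weights = np.asarray(config.donor_weights)

    normal_slot = 0
    for si in range(config.n_scaffolds):
        scaf_id = f"scaffold_{si:03d}"
        is_cont = si in cont_scaffolds
        scaffold_labels[scaf_id] = "contaminant" if is_cont else "normal"
        pieces: list[str] = []
        cursor = 0
        for gi in range(config.genes_per_scaffold):
            gap = int(rng.integers(100, 400))
            pieces.append(_random_bases(rng, gap, config.fungal_gc))
            cursor += gap
            gene_id = f"s{si:03d}g{gi:03d}"
            if is_cont:
                label = "contaminant"
            elif normal_slot in hgt_slots:
                label = "hgt"
            else:
                label = "fungal"
            if not is_cont:
                normal_slot += 1
            bacterial_like = label != "fungal"
            group_gc = config.hgt_gc if bacterial_like else config.fungal_gc
            gene_gc = float(np.clip(rng.normal(group_gc, config.gc_sd), 0.2, 0.8))
            n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
            cds = sample_cds(
                rng,
                n_codons,
                gene_gc,
                separation=(config.composition_separation if bacterial_like else 0.0),
            )
            if bacterial_like:
                n_introns = int(
                    sample_intron_counts(
                        rng, 1, config.hgt_intronless_fraction, HGT_INTRON_LAMBDA
                    )[0]
                )
            else:
                n_introns = int(
                    sample_intron_counts(
                        rng, 1, config.fungal_intronless_fraction, FUNGAL_INTRON_LAMBDA
                    )[0]
                )
            n_introns = min(n_introns, len(cds) - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            genomic_coding = cds
            if strand == "-":
                genomic_coding = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            if n_introns:
                cuts = np.sort(
                    rng.choice(np.arange(1, len(cds)), size=n_introns, replace=False)
                )
            else:
                cuts = np.array([], dtype=int)
            exon_pieces = np.split(np.frombuffer(genomic_coding.encode(), np.uint8), cuts)
            intron_lengths = 50 + rng.geometric(1.0 / 50.0, size=n_introns)
            gene_start = cursor
            exons = []
            for ei, piece in enumerate(exon_pieces):
                piece_s = piece.tobytes().decode()
                exons.append((cursor, cursor + len(piece_s)))
                pieces.append(piece_s)
                cursor += len(piece_s)
                if ei < n_introns:
                    il = int(intron_lengths[ei])
                    pieces.append(_random_bases(rng, il, config.fungal_gc))
                    cursor += il
            gene = GeneModel(
                gene_id=gene_id,
                scaffold_id=scaf_id,
                strand=strand,
                span=(gene_start, cursor),
                exons=tuple(exons),
                cds_length=len(cds),
                protein_length=len(cds) // 3,
            )
            genes.append(gene)
            labels[gene_id] = label
            cds_map[gene_id] = cds
            if label != "fungal":
                donors[gene_id] = str(rng.choice(config.donor_groups, p=weights))
        tail = int(rng.integers(100, 400))
        pieces.append(_random_bases(rng, tail, config.fungal_gc))
        scaffold_sequences[scaf_id] = "".join(pieces)

    hgt_ids = sorted(g for g, lab in labels.items() if lab == "hgt")
    deviants = set()
    if config.deviant_gene_count:
        deviants = set(
            rng.choice(hgt_ids, size=config.deviant_gene_count, replace=False).tolist()
        )
    return SyntheticTruth(
        config=config,
        genes=genes,
        labels=labels,
        donors=donors,
        cds=cds_map,
        scaffold_sequences=scaffold_sequences,
        scaffold_labels=scaffold_labels,
        deviant_genes=deviants,
    )


def simulate_coverage(truth: SyntheticTruth) -> list[CoverageTrack]:
    """Per-base Poisson depth; contaminant scaffolds and planted deviant genes scaled."""
    config = truth.config
    rng = np.random.default_rng([config.seed, 2])
    tracks = []
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in truth.genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    for scaf_id, seq in truth.scaffold_sequences.items():
        mean = config.mean_depth
        if truth.scaffold_labels[scaf_id] == "contaminant":
            mean *= config.contaminant_depth_multiplier
        depth = rng.poisson(mean, size=len(seq))
        for g in by_scaffold.get(scaf_id, []):
            if g.gene_id in truth.deviant_genes:
                s, e = g.span
                depth[s:e] = rng.poisson(
                    mean * config.deviant_depth_multiplier, size=e - s
                )
        tracks.append(CoverageTrack(scaffold_id=scaf_id, depth=depth))
    return tracks


def emit_blast_hits(
    truth: SyntheticTruth,
) -> tuple[list[list], dict[str, tuple[str, str]]]:
    """Homology hits consistent with the planted labels, as outfmt-6 rows + taxonomy map.

    Fungal genes get 1-3 fungal hits below the screening cutoff (plus, for a
    noise fraction, an extra bacterial hit, which cannot flip the fungal
    veto); transferred and contaminant genes get bacterial-only hits from
    their planted donor group.
    """
    config = truth.config
    rng = np.random.default_rng([config.seed, 3])
    taxmap: dict[str, tuple[str, str]] = {}
    for i in range(200):
        taxmap[f"fungal_subj_{i:04d}"] = ("fungi", "fungi")
    for group in config.donor_groups:
        for i in range(100):
            taxmap[f"{group}_subj_{i:04d}"] = (group, "bacteria")

    def one_row(gene: GeneModel, subject: str, exponent: float, score: float) -> list:
        alen = gene.protein_length
        return [
            gene.gene_id, subject, round(float(rng.uniform(40, 95)), 1), alen,
            int(rng.integers(0, alen // 4 + 1)), 0, 1, alen, 1, alen,
            f"{10.0 ** -exponent:.2e}", round(score, 1),
        ]

    rows: list[list] = []
    for gene in truth.genes:
        label = truth.labels[gene.gene_id]
        n_hits = int(rng.integers(1, 4))
        exps = rng.uniform(20.0, 80.0, size=n_hits)
        scores = 100.0 + 5.0 * exps + rng.uniform(0, 10, size=n_hits)
        if label == "fungal":
            for e, sc in zip(exps, scores):
                subj = f"fungal_subj_{int(rng.integers(0, 200)):04d}"
                rows.append(one_row(gene, subj, e, sc))
            if config.noise_fraction and rng.random() < config.noise_fraction:
                group = str(rng.choice(config.donor_groups))
                subj = f"{group}_subj_{int(rng.integers(0, 100)):04d}"
                rows.append(one_row(gene, subj, float(rng.uniform(20, 80)), 200.0))
        else:
            group = truth.donors[gene.gene_id]
            for e, sc in zip(exps, scores):
                subj = f"{group}_subj_{int(rng.integers(0, 100)):04d}"
                rows.append(one_row(gene, subj, e, sc))
    return rows, taxmap


# ---------------------------------------------------------------------------
# composition cohorts (for the statistics battery at configurable n)


def simulate_composition_cohorts(
    config: SimulationConfig,
    n_per_group: int,
    seed: int | None = None,
    separation: float | None = None,
) -> dict[str, list[str]]:
    """CDS cohorts for the hgt / neighbor_fungal / all_fungal GC-mean contrasts.

    Group means follow the configured 0.4911 / 0.488 / 0.4865 targets with
    between-gene SD ``config.gc_sd``.  ``separation`` (default the config's
    ``composition_separation``) tilts the codon preferences of the hgt group
    only; 0 gives the non-separable regime.
    """
    seed = config.seed if seed is None else seed
    sep = config.composition_separation if separation is None else separation
    rng = np.random.default_rng([seed, 4])
    targets = {
        "hgt": config.hgt_gc,
        "neighbor_fungal": config.neighbor_gc,
        "all_fungal": config.fungal_gc,
    }
    out: dict[str, list[str]] = {}
    for group, mean_gc in targets.items():
        seqs = []
        gcs = np.clip(rng.normal(mean_gc, config.gc_sd, size=n_per_group), 0.2, 0.8)
        lengths = rng.integers(config.min_codons, config.max_codons + 1, size=n_per_group)
        for gc, n_codons in zip(gcs, lengths):
            seqs.append(
                sample_cds(
                    rng, int(n_codons), float(gc),
                    separation=(sep if group == "hgt" else 0.0),
                )
            )
        out[group] = seqs
    return out


#: Class frequencies of the synthetic SM ledger (NRPS-heavy, as in
#: siderophore-rich genomes).
SM_CLASS_WEIGHTS = {
    "NRPS": 0.40,
    "NRPS-like": 0.25,
    "PKS": 0.08,
    "PKS-like": 0.07,
    "NRPS-PKS hybrid": 0.02,
    "TC": 0.18,
}


def emit_sm_ledger(truth: SyntheticTruth, fraction: float = 0.15):
    """Label a random gene subset with SM core-gene classes (genome x class census input)."""
    import pandas as pd

    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng([truth.config.seed, 5])
    ids = sorted(g.gene_id for g in truth.genes)
    n = max(1, round(fraction * len(ids)))
    chosen = sorted(rng.choice(ids, size=n, replace=False).tolist())
    classes = rng.choice(
        list(SM_CLASS_WEIGHTS), size=n, p=list(SM_CLASS_WEIGHTS.values())
    )
    return pd.DataFrame(
        {"gene_id": chosen, "genome_id": "synthetic", "sm_class": classes}
    )


# ---------------------------------------------------------------------------
# plate images


def emit_plate_image(
    halo_radius_cm: float,
    dish_diameter_cm: float = 5.5,
    pixels_per_cm: float = 40.0,
    seed: int = 0,
    path: str | Path | None = None,
    noise_sd: float = 5.0,
) -> np.ndarray:
    """Render a synthetic CAS plate: teal dish, yellow central halo, speckle.

    Returns the RGB array (uint8); writes a PNG when ``path`` is given.
    """
    if halo_radius_cm < 0:
        raise ValueError("halo radius must be non-negative")
    if halo_radius_cm > dish_diameter_cm / 2:
        raise ValueError("halo radius exceeds dish radius")
    rng = np.random.default_rng(seed)
    dish_r_px = dish_diameter_cm / 2 * pixels_per_cm
    size = int(round(dish_diameter_cm * pixels_per_cm * 1.15))
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    img = np.empty((size, size, 3), dtype=float)
    img[:] = (25.0, 25.0, 25.0)  # bench background
    dish_mask = r2 <= dish_r_px**2
    img[dish_mask] = (0.0, 135.0, 150.0)  # Fe-CAS teal
    halo_r_px = halo_radius_cm * pixels_per_cm
    halo_mask = r2 <= halo_r_px**2
    img[halo_mask] = (235.0, 205.0, 45.0)  # iron-stripped yellow
    img += rng.normal(0.0, noise_sd, size=img.shape)
    out = np.clip(img, 0, 255).astype(np.uint8)
    if path is not None:
        Image.fromarray(out).save(str(path), format="PNG")
    return out


def write_screen_inputs(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Emit every file the screen stage ingests; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = truth.write(outdir)
    tracks = simulate_coverage(truth)
    paths["depth"] = outdir / "depth.tsv"
    io_formats.write_depth(tracks, paths["depth"])
    rows, taxmap = emit_blast_hits(truth)
    paths["hits"] = outdir / "hits.tsv"
    io_formats.write_blast6(rows, paths["hits"])
    paths["taxmap"] = outdir / "taxmap.tsv"
    io_formats.write_taxonomy_map(taxmap, paths["taxmap"])
    return paths
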