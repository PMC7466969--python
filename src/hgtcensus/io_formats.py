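"""Readers and writers for the standard formats the pipeline touches.

All genomic intervals are 0-based half-open internally.  GFF3 and HMMER
domtblout coordinates (1-based inclusive) are converted at the boundary and
converted back on write, so ``to_gff(from_gff(x)) == x``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

#: BLAST tabular (outfmt 6) default columns.
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def from_gff_interval(start: int, end: int) -> Interval:
    """Convert a 1-based inclusive (GFF3/domtblout) interval to 0-based half-open."""
    return (start - 1, end)


def to_gff_interval(interval: Interval) -> tuple[int, int]:
    """Inverse of :func:`from_gff_interval`."""
    start, end = interval
    return (start + 1, end)


@dataclass(frozen=True)
class GeneModel:
    """A gene model: scaffold placement, exon structure and CDS size.

    ``span`` and ``exons`` are 0-based half-open genomic intervals on
    ``scaffold_id``; exons are sorted, non-overlapping and contained in the
    span.  This is the unit every downstream filter acts on.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    span: Interval
    exons: tuple[Interval, ...]
    cds_length: int
    protein_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        s, e = self.span
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs >=1 exon")
        prev_end = None
        for xs, xe in self.exons:
            if xe <= xs:
                raise ValueError(f"{self.gene_id}: empty exon ({xs},{xe})")
            if xs < s or xe > e:
                raise ValueError(f"{self.gene_id}: exon ({xs},{xe}) outside span {self.span}")
            if prev_end is not None and xs < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = xe
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not a multiple of 3")

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Gaps between consecutive exons."""
        out = []
        for (a, b) in zip(self.exons, self.exons[1:]):
            out.append((a[1], b[0]))
        return tuple(out)


@dataclass(frozen=True)
class HitRecord:
    """One homology hit with its subject's taxonomy assignment."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    taxonomy_group: str
    superkingdom: str  # fungi | bacteria | other

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}->{self.subject_id}")
        if not self.taxonomy_group:
            raise ValueError("taxonomy_group must be nonempty")


@dataclass
class CoverageTrack:
    """Per-base read depth along one scaffold."""

    scaffold_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError(f"{self.scaffold_id}: negative depth values")

    @property
    def mean(self) -> float:
        return float(self.depth.mean())


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain hit on a protein (0-based half-open envelope)."""

    query_id: str
    domain_name: str
    interval: Interval
    score: float


# ---------------------------------------------------------------------------
# GFF3


def _prescan_gff3(path: str | Path) -> None:
    """Validate Parent references line by line so errors can name the line."""
    defined: set[str] = set()
    referenced: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" in attrs:
                defined.add(attrs["ID"])
            if "Parent" in attrs:
                for parent in attrs["Parent"].split(","):
                    referenced.append((lineno, parent))
    for lineno, parent in referenced:
        if parent not in defined:
            raise ValueError(f"{path}:{lineno}: Parent={parent} refers to an undefined feature")


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` records.

    The canonical transcript of each gene is the mRNA with the longest total
    CDS, ties broken lexicographically by transcript ID.  Coordinates are
    converted to 0-based half-open.
    """
    path = str(path)
    _prescan_gff3(path)
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best = None  # (cds_len, transcript_id, exons)
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                from_gff_interval(f.start, f.end)
                for f in db.children(mrna, featuretype="exon")
            )
            cds_parts = sorted(
                from_gff_interval(f.start, f.end)
                for f in db.children(mrna, featuretype="CDS")
            )
            if not exons:
                exons = cds_parts
            for (a, b) in zip(exons, exons[1:]):
                if b[0] < a[1]:
                    raise ValueError(
                        f"{path}: overlapping exons in transcript {mrna.id}"
                    )
            cds_len = sum(e - s for s, e in cds_parts)
            key = (-cds_len, str(mrna.id))
            if best is None or key < best[0]:
                best = (key, exons, cds_len)
        if best is None:
            continue
        _, exons, cds_len = best
        genes.append(
            GeneModel(
                gene_id=str(gene.id),
                scaffold_id=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                span=from_gff_interval(gene.start, gene.end),
                exons=tuple(exons),
                cds_length=cds_len,
                protein_length=cds_len // 3,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal gene/mRNA/exon/CDS GFF3 file.

    A GeneModel stores only the total CDS length, not the CDS sub-intervals,
    so CDS features (equal to the exons) are emitted only for fully coding
    exon structures; otherwise just the exons are written.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold_id, g.span)):
            gs, ge = to_gff_interval(g.span)
            mrna_id = f"{g.gene_id}.t1"
            fully_coding = g.cds_length == sum(e - s for s, e in g.exons)
            fh.write(
                f"{g.scaffold_id}\thgtcensus\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.scaffold_id}\thgtcensus\tmRNA\t{gs}\t{ge}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, exon in enumerate(g.exons, start=1):
                es, ee = to_gff_interval(exon)
                fh.write(
                    f"{g.scaffold_id}\thgtcensus\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
                if fully_coding:
                    fh.write(
                        f"{g.scaffold_id}\thgtcensus\tCDS\t{es}\t{ee}\t.\t{g.strand}\t0\t"
                        f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# Gene-model TSV (round-trippable internal table)


def write_gene_models_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "scaffold_id": g.scaffold_id,
                "strand": g.strand,
                "start": g.span[0],
                "end": g.span[1],
                "exons": ",".join(f"{s}-{e}" for s, e in g.exons),
                "cds_length": g.cds_length,
                "protein_length": g.protein_length,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "scaffold_id": str})
    genes = []
    for row in df.itertuples(index=False):
        exons = tuple(
            tuple(int(x) for x in part.split("-")) for part in str(row.exons).split(",")
        )
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                scaffold_id=row.scaffold_id,
                strand=row.strand,
                span=(int(row.start), int(row.end)),
                exons=exons,  # type: ignore[arg-type]
                cds_length=int(row.cds_length),
                protein_length=int(row.protein_length),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# BLAST tabular


def read_taxonomy_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a subject->taxonomy TSV with columns subject_id, taxonomy_group, superkingdom."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        r.subject_id: (r.taxonomy_group, r.superkingdom) for r in df.itertuples(index=False)
    }


def write_taxonomy_map(taxmap: Mapping[str, tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"subject_id": k, "taxonomy_group": v[0], "superkingdom": v[1]}
            for k, v in taxmap.items()
        ]
    ).to_csv(path, sep="\t", index=False)


def parse_blast6(
    path: str | Path, taxonomy_map: Mapping[str, tuple[str, str]]
) -> list[HitRecord]:
    """Parse 12-column BLAST outfmt-6 hits, attaching taxonomy per subject.

    All rows are retained (the e-value cutoff is applied downstream).
    Subjects absent from ``taxonomy_map`` are assigned superkingdom "other"
    and logged.
    """
    records: list[HitRecord] = []
    unmapped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            qseqid, sseqid = cols[0], cols[1]
            evalue, bitscore = float(cols[10]), float(cols[11])
            if sseqid in taxonomy_map:
                group, kingdom = taxonomy_map[sseqid]
            else:
                group, kingdom = "unmapped", "other"
                unmapped += 1
            records.append(
                HitRecord(
                    query_id=qseqid,
                    subject_id=sseqid,
                    evalue=evalue,
                    bitscore=bitscore,
                    taxonomy_group=group,
                    superkingdom=kingdom,
                )
            )
    if unmapped:
        logger.warning("%s: %d hits to subjects missing from the taxonomy map", path, unmapped)
    return records


def write_blast6(rows: Iterable[Sequence], path: str | Path) -> None:
    """Write 12-column outfmt-6 rows (sequences of 12 values)."""
    with open(path, "w") as fh:
        for row in rows:
            if len(row) != 12:
                raise ValueError("outfmt 6 rows must have 12 columns")
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# samtools-depth TSV


def parse_depth(
    path: str | Path, scaffold_lengths: Mapping[str, int] | None = None
) -> list[CoverageTrack]:
    """Parse a ``samtools depth``-style TSV of (scaffold, 1-based pos, depth).

    Positions may be sparse; missing positions get depth 0.  If
    ``scaffold_lengths`` is given, tracks are padded (or created, for
    scaffolds with no rows) to the declared length.
    """
    per_scaffold: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            scaf, pos, depth = cols[0], int(cols[1]), int(cols[2])
            rows = per_scaffold.setdefault(scaf, [])
            if rows and pos <= rows[-1][0]:
                raise ValueError(
                    f"{path}:{lineno}: non-monotone position {pos} on scaffold {scaf}"
                )
            rows.append((pos, depth))
    names = list(per_scaffold)
    if scaffold_lengths is not None:
        names += [s for s in scaffold_lengths if s not in per_scaffold]
    tracks = []
    for scaf in names:
        rows = per_scaffold.get(scaf, [])
        max_pos = rows[-1][0] if rows else 0
        length = max_pos
        if scaffold_lengths is not None and scaf in scaffold_lengths:
            length = scaffold_lengths[scaf]
            if max_pos > length:
                raise ValueError(
                    f"{scaf}: depth position {max_pos} beyond declared length {length}"
                )
        depth = np.zeros(length, dtype=np.int64)
        for pos, d in rows:
            depth[pos - 1] = d
        tracks.append(CoverageTrack(scaffold_id=scaf, depth=depth))
    return tracks


def write_depth(tracks: Iterable[CoverageTrack], path: str | Path) -> None:
    """Write per-base depth, omitting zero-depth positions (samtools default)."""
    with open(path, "w") as fh:
        for track in tracks:
            (nz,) = np.nonzero(track.depth)
            for i in nz:
                fh.write(f"{track.scaffold_id}\t{i + 1}\t{track.depth[i]}\n")


# ---------------------------------------------------------------------------
# Newick / domtblout


def parse_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick tree; tip labels must be unique and number >= 2."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"{path}: duplicate tip label ({exc})") from exc
    tree.is_rooted = True
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) < 2:
        raise ValueError(f"{path}: tree has fewer than 2 tips")
    seen = set()
    for t in tips:
        if t in seen:
            raise ValueError(f"{path}: duplicate tip label {t!r}")
        seen.add(t)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def parse_domtbl(path: str | Path) -> list[DomainHit]:
    """Parse an HMMER domtblout-like table into per-domain hits.

    The target name column holds the protein (query_id here), the query name
    column the profile (domain name); envelope coordinates (columns 20-21,
    1-based inclusive) become 0-based half-open intervals.  Hits are sorted
    by (query, envelope start).
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split()
            if len(cols) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >=22 whitespace columns, got {len(cols)}"
                )
            env_from, env_to = int(cols[19]), int(cols[20])
            if env_from < 1 or env_to < env_from:
                raise ValueError(f"{path}:{lineno}: bad envelope {env_from}..{env_to}")
            hits.append(
                DomainHit(
                    query_id=cols[0],
                    domain_name=cols[3],
                    interval=from_gff_interval(env_from, env_to),
                    score=float(cols[13]),
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.interval))
    return hits


# ---------------------------------------------------------------------------
# FASTA + CDS extraction


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def extract_cds(gene: GeneModel, scaffold_seq: str) -> str:
    """Concatenate exon sequence in coding orientation (reverse-complemented on -)."""
    parts = [scaffold_seq[s:e] for s, e in gene.exons]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
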