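"""Gene structures: intron inference and classification, tandem array calls.

Family genes in plants are typically intronless in their coding sequence but
frequently carry spliceosomal introns in the untranslated regions, mostly at
the 5' UTR.  This module derives introns from exon gaps of GFF3 gene models
(introns are never read from the file), classifies each intron relative to
the translated span in a strand-aware way (five_prime_UTR / CDS /
three_prime_UTR, with "junction" as the fallback bucket), produces per-taxon
CDS-intron censuses and per-species UTR-intron summaries, and calls tandem
arrays of family genes from genomic gene ranks.

Coordinates follow the GFF3 convention: 1-based, inclusive.
"""
from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

FIVE_UTR = "five_prime_UTR"
THREE_UTR = "three_prime_UTR"
CDS_CLASS = "CDS"
JUNCTION = "junction"


@dataclass(frozen=True)
class GeneModel:
    """One gene: ordered exons, CDS segments and its ordinal genomic rank."""

    gene_id: str
    seq_region: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    rank: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            if end < start:
                raise ValueError(f"{self.gene_id}: bad exon ({start}, {end})")
            prev_end = end
        for cstart, cend in self.cds:
            if not any(s <= cstart and cend <= e for s, e in self.exons):
                raise ValueError(
                    f"{self.gene_id}: CDS segment ({cstart}, {cend}) outside exons"
                )

    @property
    def cds_span(self) -> tuple[int, int] | None:
        if not self.cds:
            return None
        return (min(s for s, _ in self.cds), max(e for _, e in self.cds))


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    start: int
    end: int
    intron_class: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TandemArray:
    seq_region: str
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# GFF3 parsing


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into gene models.

    For multi-isoform genes, the isoform with the longest total CDS is
    canonical.  Genomic rank is the ordinal position of the gene on its
    seq_region, by start coordinate.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    raw: list[tuple[str, str, str, int, tuple, tuple]] = []
    for gene in db.features_of_type("gene"):
        best_exons: tuple = ()
        best_cds: tuple = ()
        best_len = -1
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = tuple(
                sorted(
                    (f.start, f.end)
                    for f in db.children(mrna, featuretype="exon")
                )
            )
            cds = tuple(
                sorted(
                    (f.start, f.end)
                    for f in db.children(mrna, featuretype="CDS")
                )
            )
            cds_len = sum(e - s + 1 for s, e in cds)
            if cds_len > best_len:
                best_len, best_exons, best_cds = cds_len, exons, cds
        raw.append((gene.id, gene.seqid, gene.strand, gene.start, best_exons, best_cds))

    models: list[GeneModel] = []
    by_region: dict[str, list] = {}
    for rec in raw:
        by_region.setdefault(rec[1], []).append(rec)
    for region in sorted(by_region):
        for rank, rec in enumerate(sorted(by_region[region], key=lambda r: r[3]), 1):
            gene_id, seqid, strand, _, exons, cds = rec
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    seq_region=seqid,
                    strand=strand,
                    exons=exons,
                    cds=cds,
                    rank=rank,
                )
            )
    return models


# ---------------------------------------------------------------------------
# Introns


def infer_introns(gene: GeneModel) -> list[IntronRecord]:
    """Derive introns from exon gaps and classify them strand-aware.

    An intron entirely on the 5' side of the translation start is
    ``five_prime_UTR``; entirely past the stop, ``three_prime_UTR``;
    strictly inside the translated span, ``CDS``; anything else (only
    possible for degenerate annotations) falls into ``junction``.
    A single-exon gene yields an empty list (intronless).
    """
    if not gene.exons:
        raise ValueError(f"{gene.gene_id}: gene has no exons")
    introns = []
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if s2 > e1 + 1:
            introns.append((e1 + 1, s2 - 1))
    span = gene.cds_span
    records = []
    for start, end in introns:
        if span is None:
            klass = JUNCTION
        else:
            cds_start, cds_end = span
            upstream = end < cds_start
            downstream = start > cds_end
            inside = start > cds_start and end < cds_end
            if gene.strand == "+":
                five, three = upstream, downstream
            else:
                five, three = downstream, upstream
            if five:
                klass = FIVE_UTR
            elif three:
                klass = THREE_UTR
            elif inside:
                klass = CDS_CLASS
            else:
                klass = JUNCTION
        records.append(IntronRecord(gene.gene_id, start, end, klass))
    return records


def count_utr_intron_genes(
    rows: Iterable[tuple[str, str, Sequence[str]]],
) -> pd.DataFrame:
    """Per-species UTR-intron gene counts.

    ``rows`` are (gene_id, species, intron class multiset) with one row per
    gene.  Returns a frame indexed by species with columns ``any_utr``,
    ``five_utr``, ``three_utr``, ``both_utr``, ``intronless``; each gene
    counts once per category.  Duplicate gene ids are an error.
    """
    seen: set[str] = set()
    counts: dict[str, Counter] = {}
    for gene_id, species, classes in rows:
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        tally = counts.setdefault(
            species, Counter(any_utr=0, five_utr=0, three_utr=0, both_utr=0, intronless=0)
        )
        has5 = FIVE_UTR in classes
        has3 = THREE_UTR in classes
        tally["any_utr"] += has5 or has3
        tally["five_utr"] += has5
        tally["three_utr"] += has3
        tally["both_utr"] += has5 and has3
        tally["intronless"] += not classes
    frame = pd.DataFrame.from_dict(counts, orient="index").astype(int)
    if frame.empty:
        frame = pd.DataFrame(
            columns=["any_utr", "five_utr", "three_utr", "both_utr", "intronless"]
        )
    return frame


def cds_intron_census(genes_by_taxon: Mapping[str, Sequence[GeneModel]]) -> dict[str, str]:
    """Per-taxon min-max of CDS-intron counts, formatted like "0-2".

    Junction-class introns count with CDS (the conservative bucket);
    intronless genes contribute 0.
    """
    out = {}
    for taxon, genes in genes_by_taxon.items():
        counts = [
            sum(1 for r in infer_introns(g) if r.intron_class in (CDS_CLASS, JUNCTION))
            for g in genes
        ]
        if not counts:
            out[taxon] = ""
            continue
        lo, hi = min(counts), max(counts)
        out[taxon] = str(lo) if lo == hi else f"{lo}-{hi}"
    return out


# ---------------------------------------------------------------------------
# Tandem arrays


def detect_tandem_arrays(
    genes: Sequence[GeneModel],
    family_ids: Iterable[str],
    max_gap: int = 1,
) -> list[TandemArray]:
    """Maximal runs of family genes with at most ``max_gap`` intervening
    non-family genes between consecutive members on one seq_region.

    Arrays of size >= 2 are reported, sorted by seq_region then first rank.
    Family ids absent from ``genes`` produce a logged warning.
    """
    family = set(family_ids)
    known = {g.gene_id for g in genes}
    for missing in sorted(family - known):
        logger.warning("family id %s not found among gene models; ignored", missing)

    arrays: list[TandemArray] = []
    by_region: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_region.setdefault(g.seq_region, []).append(g)
    for region in sorted(by_region):
        members = sorted(
            (g for g in by_region[region] if g.gene_id in family),
            key=lambda g: g.rank,
        )
        run: list[GeneModel] = []
        for g in members:
            if run and (g.rank - run[-1].rank - 1) > max_gap:
                if len(run) >= 2:
                    arrays.append(
                        TandemArray(region, tuple(x.gene_id for x in run))
                    )
                run = []
            run.append(g)
        if len(run) >= 2:
            arrays.append(TandemArray(region, tuple(x.gene_id for x in run)))
    return arrays


# ---------------------------------------------------------------------------
# Packaged UTR-intron reference table

TABLE2_COLUMNS = ("group", "gene", "intron_location", "intron_length_nt", "cdna_clone")

_SPECIES_BY_PREFIX = {"ath": "A. thaliana", "osa": "O. sativa"}

_LOCATION_CLASSES = {
    "5'UTR": (FIVE_UTR,),
    "3'UTR": (THREE_UTR,),
    "5'UTR; 3'UTR": (FIVE_UTR, THREE_UTR),
    "intronless": (),
}


def _table2_path():
    return resources.files("zfp.data").joinpath("table2.tsv")


def load_table2() -> pd.DataFrame:
    """Load the packaged UTR-intron reference table (groups A-F of the
    A. thaliana / O. sativa family census)."""
    with resources.as_file(_table2_path()) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_table2(frame: pd.DataFrame, path: str | Path) -> None:
    """Serialize the reference table; byte-identical round trip with
    :func:`load_table2`."""
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def table2_gene_rows(frame: pd.DataFrame) -> list[tuple[str, str, tuple[str, ...]]]:
    """Expand the reference table into (gene_id, species, classes) rows.

    Class multiplicity follows the per-location length lists: lengths for
    one location are comma-separated; locations are semicolon-separated.
    """
    rows = []
    for rec in frame.itertuples(index=False):
        prefix = rec.gene.split("|")[0]
        species = _SPECIES_BY_PREFIX.get(prefix, prefix)
        locations = _LOCATION_CLASSES[rec.intron_location]
        if not locations:
            rows.append((rec.gene, species, ()))
            continue
        length_groups = [part.strip() for part in rec.intron_length_nt.split(";")]
        classes: list[str] = []
        for klass, lengths in zip(locations, length_groups):
            classes.extend([klass] * len(lengths.split(",")))
        rows.append((rec.gene, species, tuple(classes)))
    return rows
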