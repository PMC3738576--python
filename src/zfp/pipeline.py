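"""End-to-end orchestration: scan -> regions -> motifs -> tree/groups -> genes.

Each stage logs its parameters, writes its artifacts into the output
directory (TSV, MEME minimal text, newick, JSON) and feeds the next stage.
A stage failure aborts the run with the failing stage named.  Given the
same inputs, parameters and seeds, a rerun produces identical artifacts.
"""
from __future__ import annotations

import csv
import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import architecture, gene_models, motifs, phylo, zf_grammar

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and stage parameters of one pipeline run."""

    fasta: Path
    out_dir: Path
    clades: Path | None = None
    gff: Path | None = None

    run_motifs: bool = True
    run_phylo: bool = True
    run_genes: bool = True

    bzf_min_spacer: int = 6
    bzf_max_spacer: int = 26
    motif_widths: tuple[int, ...] = tuple(range(10, 21))
    max_motifs_per_region: int = 4
    motif_seed: int = 0
    motif_restarts: int = 5
    motif_max_iter: int = 100
    scan_threshold: float = 0.7
    bootstrap_reps: int = 200
    phylo_seed: int = 0
    collapse_threshold: float = 0.80
    tandem_max_gap: int = 1

    def validate(self) -> None:
        self.fasta = Path(self.fasta)
        self.out_dir = Path(self.out_dir)
        if not self.fasta.exists():
            raise FileNotFoundError(f"FASTA not found: {self.fasta}")
        for attr in ("clades", "gff"):
            value = getattr(self, attr)
            if value is not None:
                value = Path(value)
                setattr(self, attr, value)
                if not value.exists():
                    raise FileNotFoundError(f"{attr} file not found: {value}")
        if not (0 < self.collapse_threshold <= 1):
            raise ValueError("collapse_threshold must be in (0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


def _stage(name: str):
    def wrap(func):
        def inner(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return func(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - report failing stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("scan")
def _scan_stage(cfg: PipelineConfig, records: dict[str, str]):
    ring_pat = zf_grammar.make_btl_ring_pattern()
    bzf_pat = zf_grammar.make_bzf_pattern(cfg.bzf_min_spacer, cfg.bzf_max_spacer)
    logger.info(
        "scan: %d records, bzf spacer bounds [%d, %d]",
        len(records), cfg.bzf_min_spacer, cfg.bzf_max_spacer,
    )
    per_seq: dict[str, dict] = {}
    all_matches = []
    for seq_id, seq in records.items():
        rings = zf_grammar.scan(seq, ring_pat, sequence_id=seq_id)
        ring = rings[0] if rings else None
        bzf = None
        if ring is not None:
            for cand in zf_grammar.scan(seq, bzf_pat, sequence_id=seq_id):
                if cand.end < ring.start:
                    bzf = cand
                    break
        per_seq[seq_id] = {"ring": ring, "bzf": bzf}
        all_matches.extend(m for m in (bzf, ring) if m is not None)
    zf_grammar.write_matches_tsv(all_matches, cfg.out_dir / "matches.tsv")
    return per_seq


@_stage("regions")
def _regions_stage(cfg: PipelineConfig, records, per_seq):
    decomps = {}
    for seq_id, found in per_seq.items():
        if found["ring"] is None:
            logger.warning("%s: no RING-H2; excluded (not a family member)", seq_id)
            continue
        decomps[seq_id] = architecture.decompose(
            seq_id, len(records[seq_id]), found["bzf"], found["ring"]
        )
    with open(cfg.out_dir / "regions.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sequence_id", "region", "start", "end"])
        for seq_id in decomps:
            for label, (start, end) in decomps[seq_id].nonempty():
                writer.writerow([seq_id, label, start, end])
    return decomps


@_stage("motifs")
def _motifs_stage(cfg: PipelineConfig, records, decomps):
    region_seqs: dict[str, list[str]] = {"III": [], "V": [], "I": []}
    for seq_id, decomp in decomps.items():
        for label in region_seqs:
            bounds = decomp.regions.get(label)
            if bounds is not None:
                fragment = records[seq_id][bounds[0] - 1 : bounds[1]]
                if len(fragment) >= min(cfg.motif_widths):
                    region_seqs[label].append(fragment)

    catalog: list[motifs.PSPM] = []
    for label, seqs in region_seqs.items():
        if len(seqs) < 5:
            logger.info("motifs: region %s has %d usable sequences; skipped", label, len(seqs))
            continue
        found = motifs.discover_motifs(
            seqs,
            widths=cfg.motif_widths,
            max_motifs=cfg.max_motifs_per_region,
            seed=cfg.motif_seed,
            n_restarts=cfg.motif_restarts,
            max_iter=cfg.motif_max_iter,
            motif_prefix=f"{label.lower()}_m",
        )
        logger.info("motifs: region %s -> %d accepted", label, len(found))
        catalog.extend(found)
    catalog = motifs.deduplicate(catalog)
    motifs.write_meme(catalog, cfg.out_dir / "motifs.meme")

    occurrences = motifs.scan_catalog(
        {sid: records[sid] for sid in decomps}, catalog, cfg.scan_threshold
    )
    profiles = architecture.build_profiles(decomps.values(), occurrences)
    labelled = []
    for prof in profiles:
        for region_label, motif_id, start in prof.occurrences:
            labelled.append((prof.sequence_id, motif_id, start, region_label))
    with open(cfg.out_dir / "occurrences.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sequence_id", "motif_id", "start", "region"])
        writer.writerows(labelled)
    with open(cfg.out_dir / "profiles.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sequence_id", "architecture"])
        for prof in profiles:
            writer.writerow([prof.sequence_id, prof.architecture])
    return catalog, profiles, labelled


@_stage("phylo")
def _phylo_stage(cfg: PipelineConfig, records, per_seq, clade_labels):
    entries = [
        (seq_id, records[seq_id], found["bzf"], found["ring"])
        for seq_id, found in per_seq.items()
    ]
    aln = phylo.build_anchored_alignment(entries)
    logger.info(
        "phylo: %d sequences, %d bootstrap replicates, seed %d",
        len(aln.ids), cfg.bootstrap_reps, cfg.phylo_seed,
    )
    tree = phylo.bootstrap_supports(
        aln, n_reps=cfg.bootstrap_reps, seed=cfg.phylo_seed
    )
    phylo.write_newick(tree, cfg.out_dir / "tree.nwk")
    groups = None
    if clade_labels:
        outgroup = [
            i for i, c in clade_labels.items() if c not in ("monocot", "eudicot")
        ]
        groups = phylo.collapse_and_group(
            tree, cfg.collapse_threshold, clade_labels, outgroup_ids=outgroup
        )
        with open(cfg.out_dir / "groups.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "group"])
            for seq_id in sorted(groups):
                writer.writerow([seq_id, groups[seq_id]])
    return groups


@_stage("genes")
def _genes_stage(cfg: PipelineConfig, family_ids):
    genes = gene_models.read_gff3(cfg.gff)
    # intron summaries describe the family; other genes only contribute
    # their genomic ranks to tandem adjacency
    family_genes = [g for g in genes if g.gene_id in family_ids]
    intron_rows = []
    by_gene: dict[str, list[str]] = {}
    for gene in family_genes:
        records = gene_models.infer_introns(gene)
        by_gene[gene.gene_id] = [r.intron_class for r in records]
        for rec in records:
            intron_rows.append(
                [gene.gene_id, rec.start, rec.end, rec.length, rec.intron_class]
            )
    with open(cfg.out_dir / "introns.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "start", "end", "length", "class"])
        writer.writerows(intron_rows)

    species_of = lambda gid: gid.split("-")[0].split("|")[0]  # noqa: E731
    utr_counts = gene_models.count_utr_intron_genes(
        (gid, species_of(gid), classes) for gid, classes in by_gene.items()
    )
    arrays = gene_models.detect_tandem_arrays(
        genes, family_ids, max_gap=cfg.tandem_max_gap
    )
    with open(cfg.out_dir / "tandem.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["seq_region", "members"])
        for arr in arrays:
            writer.writerow([arr.seq_region, ",".join(arr.members)])
    census = gene_models.cds_intron_census(
        _group_by(family_genes, key=lambda g: species_of(g.gene_id))
    )
    return utr_counts, arrays, census


def _group_by(items, key):
    out = defaultdict(list)
    for item in items:
        out[key(item)].append(item)
    return dict(out)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return (and write) the summary report."""
    config.validate()
    config.out_dir.mkdir(parents=True, exist_ok=True)
    records = zf_grammar.read_fasta(config.fasta)

    per_seq = _scan_stage(config, records)
    decomps = _regions_stage(config, records, per_seq)

    report: dict = {
        "n_sequences": len(records),
        "n_family_members": len(decomps),
        "variant_counts": dict(
            Counter(
                found["ring"].variant
                for found in per_seq.values()
                if found["ring"] is not None
            )
        ),
        "bzf_variant_counts": dict(
            Counter(
                found["bzf"].variant
                for found in per_seq.values()
                if found["bzf"] is not None
            )
        ),
    }

    if config.run_motifs:
        catalog, profiles, labelled = _motifs_stage(config, records, decomps)
        per_region = Counter(region for *_, region in labelled)
        motif_region: dict[str, Counter] = defaultdict(Counter)
        for _, motif_id, _, region in labelled:
            motif_region[motif_id][region] += 1
        logo_tally = Counter(
            counts.most_common(1)[0][0] for counts in motif_region.values()
        )
        report["motifs"] = {
            "catalog_size": len(catalog),
            "occurrences_per_region": dict(per_region),
            "logos_per_region": dict(logo_tally),
            "architecture_classes": len(
                architecture.architecture_classes(profiles)
            ),
        }

    clade_labels: dict[str, str] = {}
    if config.clades is not None:
        frame = pd.read_csv(config.clades, sep="\t")
        clade_labels = dict(zip(frame["id"], frame["clade"]))

    if config.run_phylo:
        family = {sid: found for sid, found in per_seq.items() if found["ring"]}
        groups = _phylo_stage(config, records, family, clade_labels)
        if groups is not None:
            sizes = Counter(g for g in groups.values() if g != phylo.UNCLASSIFIED)
            report["groups"] = {
                "n_groups": len(sizes),
                "sizes": dict(sorted(sizes.items())),
                "n_unclassified": sum(
                    1 for g in groups.values() if g == phylo.UNCLASSIFIED
                ),
            }

    if config.run_genes and config.gff is not None:
        family_ids = set(decomps)
        utr_counts, arrays, census = _genes_stage(config, family_ids)
        report["genes"] = {
            "utr_intron_counts": {
                sp: {k: int(v) for k, v in row.items()}
                for sp, row in utr_counts.iterrows()
            },
            "tandem_arrays": [list(a.members) for a in arrays],
            "cds_intron_census": census,
        }

    (config.out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    _write_text_report(report, config.out_dir / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["zfp pipeline summary", "====================", ""]
    lines.append(f"sequences scanned:    {report['n_sequences']}")
    lines.append(f"family members:       {report['n_family_members']}")
    lines.append(f"RING-H2 variants:     {report['variant_counts']}")
    lines.append(f"BZF variants:         {report['bzf_variant_counts']}")
    if "motifs" in report:
        m = report["motifs"]
        lines.append("")
        lines.append(f"motif catalog size:   {m['catalog_size']}")
        lines.append(f"logos per region:     {m['logos_per_region']}")
        lines.append(f"architecture classes: {m['architecture_classes']}")
    if "groups" in report:
        g = report["groups"]
        lines.append("")
        lines.append(f"groups recovered:     {g['n_groups']}")
        lines.append(f"group sizes:          {g['sizes']}")
        lines.append(f"unclassified leaves:  {g['n_unclassified']}")
    if "genes" in report:
        ge = report["genes"]
        lines.append("")
        lines.append(f"UTR-intron counts:    {ge['utr_intron_counts']}")
        lines.append(f"tandem arrays:        {ge['tandem_arrays']}")
        lines.append(f"CDS-intron census:    {ge['cds_intron_census']}")
    path.write_text("\n".join(lines) + "\n")
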