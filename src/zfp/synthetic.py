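"""Seeded synthetic proteomes and gene models with planted family structure.

The generator emulates the statistical structure of the BZF/RING-H2 family:
every planted protein carries a C2/C2 BZF near the N-terminus and a RING-H2
toward the C-terminus, separated by a motif-bearing inter-finger region.
Groups radiate from a star: each group has its own random domain-gap
templates and region-III/V motif consensuses, and species members are
derived from the group ancestor by per-site substitution that never touches
ligand positions.  BZF inter-pair spacers concentrate in 11-19 residues
(97% by default) with a small tail across 6-26; RING-H2 spacings follow a
canonical/ATL-like/insertion-variant mixture.  Gene models place the genes
on per-species scaffolds with group-correlated 5'/3'-UTR introns and a
configurable number of planted two-gene tandem arrays; a machine-readable
truth table ties everything together.

Backgrounds, motif consensuses, variable-gap fillers and substitution
proposals all exclude C and H, which makes the planted ligand placement the
only grammar-legal one (the inter-finger region is always longer than the
widest allowed RING gap), so scanner truth is unambiguous by construction.
"""
from __future__ import annotations

import json
import tempfile
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gene_models as gm
from .zf_grammar import make_btl_ring_pattern

#: Average amino-acid composition of well-annotated proteomes.
BACKGROUND_FREQS = {
    "A": 0.078, "C": 0.019, "D": 0.053, "E": 0.063, "F": 0.039,
    "G": 0.072, "H": 0.023, "I": 0.053, "K": 0.059, "L": 0.091,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.068, "T": 0.059, "V": 0.066, "W": 0.014, "Y": 0.032,
}

_BG_ALPHABET = [aa for aa in BACKGROUND_FREQS if aa not in "CH"]
_BG_WEIGHTS = np.array([BACKGROUND_FREQS[aa] for aa in _BG_ALPHABET])
_BG_WEIGHTS = _BG_WEIGHTS / _BG_WEIGHTS.sum()


class SimulationError(ValueError):
    """Raised when a simulation plan is impossible or truth checking fails."""


@dataclass
class SimConfig:
    """Knobs of the synthetic family; defaults reproduce the study conditions
    the pipeline is exercised on.

    Spacer mass: 97% uniform on [11, 19], 3% spread over [6, 10] and
    [20, 26].  RING-H2 variants: 90% canonical, 5% ATL-like, 5% insertion.
    Intron plan (per group index): groups 0-1 carry a 5'UTR intron with
    probability 0.9, groups 2 and 4 are intronless, group 3 mixes 5' and 3'
    UTR introns and group 5 favours 3'UTR introns.
    """

    seed: int = 0
    n_monocots: int = 3
    n_eudicots: int = 3
    n_outgroup: int = 1
    n_groups: int = 6
    genes_per_species_per_group: int = 1
    spacer_core: tuple[int, int] = (11, 19)
    spacer_tail: tuple[int, int] = (6, 26)
    spacer_tail_prob: float = 0.03
    variant_probs: dict = field(
        default_factory=lambda: {
            "canonical_btl": 0.90,
            "atl_like": 0.05,
            "insertion_variant": 0.05,
        }
    )
    substitution_prob: float = 0.05
    group_divergence: float = 0.5
    outgroup_divergence: float = 0.7
    motif_width: int = 15
    universal_motif_width: int = 12
    motif_mutation_prob: float = 0.05
    intron_plan: dict = field(
        default_factory=lambda: {
            0: (0.9, 0.0),
            1: (0.9, 0.0),
            2: (0.0, 0.0),
            3: (0.5, 0.4),
            4: (0.0, 0.0),
            5: (0.0, 0.6),
        }
    )
    n_tandem_arrays: int = 2

    def validate(self) -> None:
        if self.n_groups < 1:
            raise SimulationError("n_groups must be >= 1")
        if not (0 <= self.spacer_tail_prob <= 1):
            raise SimulationError("spacer_tail_prob must be a probability")
        if not (6 <= self.spacer_tail[0] <= self.spacer_core[0]
                <= self.spacer_core[1] <= self.spacer_tail[1] <= 26):
            raise SimulationError("spacer support must be nested within [6, 26]")
        if abs(sum(self.variant_probs.values()) - 1.0) > 1e-9:
            raise SimulationError("variant probabilities must sum to 1")
        for p in (self.substitution_prob, self.group_divergence, self.outgroup_divergence):
            if not (0 <= p <= 1):
                raise SimulationError("divergence values must be probabilities")
        for p5, p3 in self.intron_plan.values():
            if not (0 <= p5 <= 1 and 0 <= p3 <= 1):
                raise SimulationError("intron probabilities must be in [0, 1]")
        n_family = (
            (self.n_monocots + self.n_eudicots)
            * self.n_groups
            * self.genes_per_species_per_group
        )
        if self.n_tandem_arrays > n_family:
            raise SimulationError("more tandem arrays than family genes")

    @property
    def species(self) -> list[tuple[str, str]]:
        names = [(f"mon{i + 1}", "monocot") for i in range(self.n_monocots)]
        names += [(f"eud{i + 1}", "eudicot") for i in range(self.n_eudicots)]
        names += [(f"alg{i + 1}", "chlorophyte") for i in range(self.n_outgroup)]
        return names

    @property
    def group_names(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_groups)]


@dataclass
class SimulationResult:
    config: SimConfig
    proteins: dict[str, str]
    clades: dict[str, str]
    genes: list[gm.GeneModel]
    gff_text: str
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _bg(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(_BG_ALPHABET), size=length, p=_BG_WEIGHTS)
    return "".join(_BG_ALPHABET[i] for i in idx)


def _mutate(
    rng: np.random.Generator,
    s: str,
    prob: float,
    protected: Sequence[int] = (),
) -> str:
    """Per-site substitution from the C/H-free alphabet; 1-based positions in
    ``protected`` (ligands) are never touched."""
    if prob <= 0 or not s:
        return s
    chars = list(s)
    hits = rng.random(len(chars)) < prob
    shielded = {p - 1 for p in protected}
    for k in np.flatnonzero(hits):
        if int(k) in shielded:
            continue
        chars[k] = _BG_ALPHABET[int(rng.integers(len(_BG_ALPHABET)))]
    return "".join(chars)


def _sample_spacer(rng: np.random.Generator, cfg: SimConfig) -> int:
    if rng.random() < cfg.spacer_tail_prob:
        lo_tail = list(range(cfg.spacer_tail[0], cfg.spacer_core[0]))
        hi_tail = list(range(cfg.spacer_core[1] + 1, cfg.spacer_tail[1] + 1))
        pool = lo_tail + hi_tail or list(range(cfg.spacer_core[0], cfg.spacer_core[1] + 1))
        return int(pool[int(rng.integers(len(pool)))])
    return int(rng.integers(cfg.spacer_core[0], cfg.spacer_core[1] + 1))


@dataclass
class _GroupTemplates:
    bzf_gap1: str
    bzf_gap2: str
    spacer: str
    ring_gaps_fixed: tuple[str, str, str, str, str]  # lengths 2,1,2,2,2
    g2: str  # 34 residues; prefixes used
    g6: str  # 11 residues
    motif3: str
    motif5: str


def _make_templates(rng: np.random.Generator, cfg: SimConfig) -> _GroupTemplates:
    return _GroupTemplates(
        bzf_gap1=_bg(rng, 2),
        bzf_gap2=_bg(rng, 2),
        spacer=_bg(rng, 26),
        ring_gaps_fixed=(_bg(rng, 2), _bg(rng, 1), _bg(rng, 2), _bg(rng, 2), _bg(rng, 2)),
        g2=_bg(rng, 34),
        g6=_bg(rng, 11),
        motif3=_bg(rng, cfg.motif_width),
        motif5=_bg(rng, cfg.motif_width),
    )


def _derive_templates(
    rng: np.random.Generator,
    cfg: SimConfig,
    ancestor: _GroupTemplates,
    divergence: float,
) -> _GroupTemplates:
    """Level-one evolution: domain templates descend from the family
    ancestor by per-site substitution; the region-III/V motif consensuses
    are drawn fresh so every group has a distinctive motif."""

    def mut(s: str) -> str:
        return _mutate(rng, s, divergence)

    return _GroupTemplates(
        bzf_gap1=mut(ancestor.bzf_gap1),
        bzf_gap2=mut(ancestor.bzf_gap2),
        spacer=mut(ancestor.spacer),
        ring_gaps_fixed=tuple(mut(s) for s in ancestor.ring_gaps_fixed),
        g2=mut(ancestor.g2),
        g6=mut(ancestor.g6),
        motif3=_bg(rng, cfg.motif_width),
        motif5=_bg(rng, cfg.motif_width),
    )


def _build_protein(
    rng: np.random.Generator,
    cfg: SimConfig,
    tpl: _GroupTemplates,
    universal: tuple[str, str],
    group: str,
) -> dict:
    """Assemble one protein and its truth entry from group templates."""
    sub = cfg.substitution_prob
    variant = str(
        rng.choice(list(cfg.variant_probs), p=list(cfg.variant_probs.values()))
    )
    if variant == "canonical_btl":
        g2len, g6len = 14, 10
    elif variant == "atl_like":
        g2len, g6len = 15, 10
    else:
        g2len, g6len = 14 + int(rng.integers(2, 21)), 10
    spacer_len = _sample_spacer(rng, cfg)

    parts: list[str] = []
    pos = 0

    def emit(fragment: str) -> int:
        nonlocal pos
        start = pos + 1
        parts.append(fragment)
        pos += len(fragment)
        return start

    motif_occurrences: list[tuple[str, int]] = []

    emit(_bg(rng, int(rng.integers(12, 31))))  # region I

    bzf_positions = []
    bzf_positions.append(emit("C"))
    emit(_mutate(rng, tpl.bzf_gap1, sub))
    bzf_positions.append(emit("C"))
    emit(_mutate(rng, tpl.spacer[:spacer_len], sub))
    bzf_positions.append(emit("C"))
    emit(_mutate(rng, tpl.bzf_gap2, sub))
    bzf_positions.append(emit("C"))

    # region III: group motif, then the two universal motifs next to the RING
    emit(_bg(rng, int(rng.integers(8, 21))))
    motif_occurrences.append(
        (f"{group}_III", emit(_mutate(rng, tpl.motif3, cfg.motif_mutation_prob)))
    )
    emit(_bg(rng, int(rng.integers(6, 13))))
    motif_occurrences.append(
        ("u1", emit(_mutate(rng, universal[0], cfg.motif_mutation_prob)))
    )
    emit(_bg(rng, int(rng.integers(4, 9))))
    motif_occurrences.append(
        ("u2", emit(_mutate(rng, universal[1], cfg.motif_mutation_prob)))
    )
    emit(_bg(rng, int(rng.integers(2, 6))))

    rg = tpl.ring_gaps_fixed
    ring_positions = []
    ring_positions.append(emit("C"))
    emit(_mutate(rng, rg[0], sub))
    ring_positions.append(emit("C"))
    emit(_mutate(rng, tpl.g2[:g2len], sub))
    ring_positions.append(emit("C"))
    emit(_mutate(rng, rg[1], sub))
    ring_positions.append(emit("H"))
    emit(_mutate(rng, rg[2], sub))
    ring_positions.append(emit("H"))
    emit(_mutate(rng, rg[3], sub))
    ring_positions.append(emit("C"))
    emit(_mutate(rng, tpl.g6[:g6len], sub))
    ring_positions.append(emit("C"))
    emit(_mutate(rng, rg[4], sub))
    ring_positions.append(emit("C"))

    emit(_bg(rng, int(rng.integers(4, 11))))  # region V
    motif_occurrences.append(
        (f"{group}_V", emit(_mutate(rng, tpl.motif5, cfg.motif_mutation_prob)))
    )
    emit(_bg(rng, int(rng.integers(5, 16))))

    return {
        "sequence": "".join(parts),
        "bzf_positions": bzf_positions,
        "ring_positions": ring_positions,
        "ring_variant": variant,
        "spacer": spacer_len,
        "motif_occurrences": motif_occurrences,
    }


# ---------------------------------------------------------------------------
# Gene layout


def _gene_segments(
    protein_len: int,
    has5: bool,
    has3: bool,
    cds_intron_len: int,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Transcript-order segments: (kind, length); kind 'i*' marks introns."""
    cds_len = 3 * protein_len + 3
    segs: list[tuple[str, int]] = []
    if has5:
        segs += [("u5", 30), ("i5", int(rng.integers(80, 901))), ("u5", 30)]
    else:
        segs.append(("u5", 60))
    if cds_intron_len > 0:
        half = cds_len // 2
        segs += [("cds", half), ("icds", cds_intron_len), ("cds", cds_len - half)]
    else:
        segs.append(("cds", cds_len))
    if has3:
        segs += [("u3", 30), ("i3", int(rng.integers(80, 901))), ("u3", 30)]
    else:
        segs.append(("u3", 60))
    return segs


_INTRON_CLASS = {"i5": gm.FIVE_UTR, "icds": gm.CDS_CLASS, "i3": gm.THREE_UTR}


def _lay_out_gene(
    gene_id: str,
    seqid: str,
    strand: str,
    start: int,
    segs: list[tuple[str, int]],
) -> tuple[gm.GeneModel, list[str], list[dict], int]:
    """Place transcript segments on the genome; returns the model, GFF3
    lines, truth introns and the gene end coordinate."""
    genomic = segs if strand == "+" else list(reversed(segs))
    cursor = start
    placed: list[tuple[str, int, int]] = []
    for kind, length in genomic:
        placed.append((kind, cursor, cursor + length - 1))
        cursor += length
    end = cursor - 1

    exons: list[tuple[int, int]] = []
    for kind, s, e in placed:
        if kind.startswith("i"):
            continue
        if exons and exons[-1][1] + 1 == s:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))
    cds = [(s, e) for kind, s, e in placed if kind == "cds"]
    utr5 = [(s, e) for kind, s, e in placed if kind == "u5"]
    utr3 = [(s, e) for kind, s, e in placed if kind == "u3"]
    introns = [
        {"start": s, "end": e, "class": _INTRON_CLASS[kind]}
        for kind, s, e in placed
        if kind.startswith("i")
    ]

    lines = [
        f"{seqid}\tzfp_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}",
        f"{seqid}\tzfp_sim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
        f"ID={gene_id}.m1;Parent={gene_id}",
    ]
    for s, e in exons:
        lines.append(
            f"{seqid}\tzfp_sim\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={gene_id}.m1"
        )
    cds_in_order = cds if strand == "+" else list(reversed(cds))
    phase = 0
    for s, e in cds_in_order:
        lines.append(
            f"{seqid}\tzfp_sim\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\tParent={gene_id}.m1"
        )
        phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    for s, e in utr5:
        lines.append(
            f"{seqid}\tzfp_sim\tfive_prime_UTR\t{s}\t{e}\t.\t{strand}\t.\t"
            f"Parent={gene_id}.m1"
        )
    for s, e in utr3:
        lines.append(
            f"{seqid}\tzfp_sim\tthree_prime_UTR\t{s}\t{e}\t.\t{strand}\t.\t"
            f"Parent={gene_id}.m1"
        )
    model = gm.GeneModel(
        gene_id=gene_id,
        seq_region=seqid,
        strand=strand,
        exons=tuple(exons),
        cds=tuple(cds),
    )
    return model, lines, introns, end


# ---------------------------------------------------------------------------
# Top-level simulation


def simulate(config: SimConfig, out_dir: str | Path | None = None) -> SimulationResult:
    """Generate the synthetic family; deterministic given ``config.seed``.

    Returns proteins, clade labels, gene models, GFF3 text and the truth
    table; when ``out_dir`` is given, writes ``proteins.fasta``,
    ``genes.gff3``, ``clades.tsv`` and ``truth.json`` there.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = config.group_names
    universal = (
        _bg(rng, config.universal_motif_width),
        _bg(rng, config.universal_motif_width),
    )
    ancestor = _make_templates(rng, config)
    templates = {
        g: _derive_templates(rng, config, ancestor, config.group_divergence)
        for g in groups
    }
    out_templates = _derive_templates(
        rng, config, ancestor, config.outgroup_divergence
    )

    proteins: dict[str, str] = {}
    clades: dict[str, str] = {}
    truth_proteins: dict[str, dict] = {}
    order: list[tuple[str, str, str]] = []  # (protein_id, species, group)

    for species, clade in config.species:
        is_outgroup = clade not in ("monocot", "eudicot")
        sp_groups = ["out"] if is_outgroup else groups
        for group in sp_groups:
            tpl = out_templates if group == "out" else templates[group]
            n_genes = 1 if is_outgroup else config.genes_per_species_per_group
            for k in range(n_genes):
                pid = f"{species}-{group}-{k + 1}"
                built = _build_protein(rng, config, tpl, universal, group)
                proteins[pid] = built["sequence"]
                clades[pid] = clade
                truth_proteins[pid] = {
                    "group": group,
                    "clade": clade,
                    "species": species,
                    "bzf_positions": built["bzf_positions"],
                    "ring_positions": built["ring_positions"],
                    "ring_variant": built["ring_variant"],
                    "spacer": built["spacer"],
                    "motif_occurrences": built["motif_occurrences"],
                }
                order.append((pid, species, group))

    # Planted tandem duplicates: a mutated copy laid immediately downstream.
    tandem_arrays: list[tuple[str, str]] = []
    plant_order = [rec for rec in order if truth_proteins[rec[0]]["group"] != "out"]
    for a in range(config.n_tandem_arrays):
        pid, species, group = plant_order[
            (a * (len(plant_order) // max(config.n_tandem_arrays, 1)))
            % len(plant_order)
        ]
        dup_id = f"{pid}-t"
        if dup_id in proteins:
            raise SimulationError(f"tandem plan collides on {dup_id}")
        src = truth_proteins[pid]
        dup_seq = _mutate(
            rng,
            proteins[pid],
            config.substitution_prob,
            protected=src["bzf_positions"] + src["ring_positions"],
        )
        proteins[dup_id] = dup_seq
        clades[dup_id] = clades[pid]
        truth_proteins[dup_id] = dict(src, motif_occurrences=src["motif_occurrences"])
        tandem_arrays.append((pid, dup_id))

    # Genes: per-species scaffolds, sequential layout, duplicates adjacent.
    gff_lines = ["##gff-version 3"]
    genes: list[gm.GeneModel] = []
    truth_genes: dict[str, dict] = {}
    dup_after = {src: dup for src, dup in tandem_arrays}

    for species, clade in config.species:
        seqid = f"chr_{species}"
        cursor = 1001
        idx = 0
        n_filler = 0
        members = [rec for rec in order if rec[1] == species]
        for pid, _, group in members:
            # non-family filler genes keep family loci non-adjacent, so only
            # the planted duplicates form tandem runs
            for _ in range(2 + int(rng.integers(0, 3))):
                n_filler += 1
                filler_id = f"{species}-filler-{n_filler}"
                segs = _gene_segments(100, False, False, 0, rng)
                model, lines, _, end = _lay_out_gene(
                    filler_id, seqid, "+" if idx % 2 == 0 else "-", cursor, segs
                )
                genes.append(model)
                gff_lines.extend(lines)
                cursor = end + 500
                idx += 1
            for gene_id in ([pid, dup_after[pid]] if pid in dup_after else [pid]):
                strand = "+" if idx % 2 == 0 else "-"
                if group == "out":
                    has5 = has3 = False
                    cds_intron = int(rng.integers(60, 301))
                else:
                    gidx = groups.index(group)
                    p5, p3 = config.intron_plan.get(gidx, (0.0, 0.0))
                    has5 = bool(rng.random() < p5)
                    has3 = bool(rng.random() < p3)
                    cds_intron = 0
                segs = _gene_segments(
                    len(proteins[gene_id]), has5, has3, cds_intron, rng
                )
                model, lines, introns, end = _lay_out_gene(
                    gene_id, seqid, strand, cursor, segs
                )
                genes.append(model)
                gff_lines.extend(lines)
                truth_genes[gene_id] = {"introns": introns}
                cursor = end + 500
                idx += 1

    # assign ranks per region by start order (layout is already ordered)
    ranked: list[gm.GeneModel] = []
    rank_counter: dict[str, int] = {}
    for g in genes:
        r = rank_counter.get(g.seq_region, 0) + 1
        rank_counter[g.seq_region] = r
        ranked.append(
            gm.GeneModel(
                gene_id=g.gene_id,
                seq_region=g.seq_region,
                strand=g.strand,
                exons=g.exons,
                cds=g.cds,
                rank=r,
            )
        )
    genes = ranked

    truth = {
        "proteins": truth_proteins,
        "genes": truth_genes,
        "tandem_arrays": [list(pair) for pair in tandem_arrays],
    }
    result = SimulationResult(
        config=config,
        proteins=proteins,
        clades=clades,
        genes=genes,
        gff_text="\n".join(gff_lines) + "\n",
        truth=truth,
    )
    if out_dir is not None:
        result.paths = _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: SimulationResult, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "proteins.fasta"
    with open(fasta, "w") as fh:
        for pid, seq in result.proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    gff = out_dir / "genes.gff3"
    gff.write_text(result.gff_text)
    clades = out_dir / "clades.tsv"
    with open(clades, "w") as fh:
        fh.write("id\tclade\n")
        for pid, clade in result.clades.items():
            fh.write(f"{pid}\t{clade}\n")
    truth = out_dir / "truth.json"
    truth.write_text(json.dumps(result.truth, indent=1, sort_keys=True) + "\n")
    return {"fasta": fasta, "gff": gff, "clades": clades, "truth": truth}


# ---------------------------------------------------------------------------
# Truth checking


def truth_check(result: SimulationResult) -> dict:
    """Verify the emitted outputs against the truth table.

    Asserts that every truth ligand position holds the required C/H, that
    GFF3-derived introns match the planted classes and coordinates, and that
    planted tandem members are adjacent on their scaffold.  Raises
    :class:`SimulationError` naming the first offending record.
    """
    ring = make_btl_ring_pattern()
    for pid, entry in result.truth["proteins"].items():
        seq = result.proteins.get(pid)
        if seq is None:
            raise SimulationError(f"protein {pid} missing from FASTA output")
        for pos in entry["bzf_positions"]:
            if seq[pos - 1] != "C":
                raise SimulationError(
                    f"protein {pid}: BZF ligand at {pos} is {seq[pos - 1]!r}, not C"
                )
        for pos, cls in zip(entry["ring_positions"], ring.ligands):
            if seq[pos - 1] != cls:
                raise SimulationError(
                    f"protein {pid}: RING ligand at {pos} is {seq[pos - 1]!r}, not {cls}"
                )

    with tempfile.TemporaryDirectory() as tmp:
        gff_path = Path(tmp) / "genes.gff3"
        gff_path.write_text(result.gff_text)
        parsed = {g.gene_id: g for g in gm.read_gff3(gff_path)}
    for gene_id, entry in result.truth["genes"].items():
        model = parsed.get(gene_id)
        if model is None:
            raise SimulationError(f"gene {gene_id} missing from GFF3 output")
        found = {
            (r.start, r.end, r.intron_class) for r in gm.infer_introns(model)
        }
        expected = {
            (i["start"], i["end"], i["class"]) for i in entry["introns"]
        }
        if found != expected:
            raise SimulationError(
                f"gene {gene_id}: introns {sorted(found)} != truth {sorted(expected)}"
            )

    rank_of = {g.gene_id: (g.seq_region, g.rank) for g in result.genes}
    for first, second in result.truth["tandem_arrays"]:
        r1, r2 = rank_of.get(first), rank_of.get(second)
        if r1 is None or r2 is None or r1[0] != r2[0] or abs(r1[1] - r2[1]) != 1:
            raise SimulationError(
                f"tandem array ({first}, {second}) is not adjacent on one scaffold"
            )
    return {
        "proteins": len(result.truth["proteins"]),
        "genes": len(result.truth["genes"]),
        "tandem_arrays": len(result.truth["tandem_arrays"]),
    }
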