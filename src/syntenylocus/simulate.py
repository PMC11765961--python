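"""Synthetic-data generation with machine-readable ground truth.

Every pipeline stage is testable offline: multi-species annotation panels
with a planted anchor-target-paralog arrangement (emulating the
AKAP17A / ASMT / ASMTL microsynteny), GC-rich coding sequences of exact
composition, proteins with planted domain motifs, templates with planted
primer sites, and cDNAs with specified exons dropped.  All generators are
pure functions of their parameters and a seed.

Decoy gene symbols are drawn from a panel-wide namespace (``DECOY####``)
disjoint from anchor symbols, and every decoy symbol occurs exactly once in
every species (at a random position), so a decoy adjacent to the target in
one species cannot accrue cross-species support.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .models import AnnotationSet, GeneRecord, Strand
from .synteny import ANY, OPPOSITE, SAME, AnchorConstraint, SyntenyPattern

DEFAULT_TARGET_SYMBOL = "ASMT"
DEFAULT_PLACEHOLDER_SYMBOL = "LOC900000001"


def default_asmt_pattern() -> SyntenyPattern:
    """The conserved arrangement around ASMT: AKAP17A immediately adjacent
    in the same orientation, the paralog ASMTL immediately adjacent in the
    opposite orientation."""
    return SyntenyPattern(
        target_symbol=DEFAULT_TARGET_SYMBOL,
        constraints=(
            AnchorConstraint(
                anchor_symbol="AKAP17A",
                max_rank=1,
                relative_orientation=SAME,
                support=1.0,
            ),
            AnchorConstraint(
                anchor_symbol="ASMTL",
                max_rank=1,
                relative_orientation=OPPOSITE,
                support=1.0,
            ),
        ),
        min_support_used=0.8,
    )


@dataclass(frozen=True)
class PanelSpec:
    """Study conditions for a synthetic cross-species panel.

    Gene lengths are drawn longer than intergenic gaps (gene-dense
    PAR-like neighbourhood), so rank-1 neighbours are also the bp-nearest
    genes."""

    n_species: int = 10
    pattern: SyntenyPattern = field(default_factory=default_asmt_pattern)
    n_decoys_per_scaffold: int = 20
    scaffold_length_bp: int = 2_000_000
    gene_length_range: tuple[int, int] = (2_000, 5_000)
    intergenic_range: tuple[int, int] = (200, 2_000)
    misannotate_target: bool = False
    constraint_ablation: Mapping[str, Sequence[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_decoys_per_scaffold < 0:
            raise ValueError("counts must be positive")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("bad gene_length_range")
        if self.intergenic_range[0] > self.intergenic_range[1]:
            raise ValueError("bad intergenic_range")


@dataclass
class TargetLocus:
    seq_id: str
    start: int
    end: int
    strand: str
    symbol: str


@dataclass
class GroundTruth:
    """Everything the test suite needs to verify downstream results."""

    target_symbol: str = ""
    target_locus: dict[str, TargetLocus] = field(default_factory=dict)
    constraint_satisfaction: dict[str, dict[str, bool]] = field(default_factory=dict)
    decoy_symbols: list[str] = field(default_factory=list)
    domain_positions: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    dropped_exons: dict[str, list[int]] = field(default_factory=dict)
    primer_site_distances: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), indent=1, default=_default)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        gt = cls(**{**raw, "target_locus": {}})
        gt.target_locus = {
            sp: TargetLocus(**loc) for sp, loc in raw["target_locus"].items()
        }
        gt.domain_positions = {
            k: [tuple(v) for v in vs] for k, vs in raw["domain_positions"].items()
        }
        return gt


def _anchor_strand(target_strand: Strand, orientation: str, rng: np.random.Generator) -> Strand:
    if orientation == SAME:
        return target_strand
    if orientation == OPPOSITE:
        return target_strand.flipped()
    return Strand.FORWARD if rng.integers(2) == 0 else Strand.REVERSE


def generate_panel(spec: PanelSpec) -> tuple[list[AnnotationSet], GroundTruth]:
    """Generate one annotation set per species with the pattern planted.

    The anchor-target-paralog block is contiguous in gene order: the first
    constraint's anchor immediately left of the target, the second
    immediately right, further anchors alternating outwards.  Ablating a
    constraint for a species deletes that anchor gene, making the
    constraint unsatisfiable there.  Deterministic per seed.
    """
    pattern = spec.pattern
    truth = GroundTruth(target_symbol=pattern.target_symbol)
    truth.decoy_symbols = [
        f"DECOY{i + 1:04d}" for i in range(spec.n_decoys_per_scaffold)
    ]
    panel: list[AnnotationSet] = []
    for si in range(spec.n_species):
        rng = np.random.default_rng([spec.seed % (2**31), si])
        species = f"species{si + 1:02d}"
        seq_id = f"scf_{species}"
        ann = AnnotationSet(species=species, assembly=f"asm_{species}")

        ablated = {s.upper() for s in spec.constraint_ablation.get(species, [])}
        target_strand = Strand.FORWARD if rng.integers(2) == 0 else Strand.REVERSE
        target_symbol = (
            DEFAULT_PLACEHOLDER_SYMBOL if spec.misannotate_target else pattern.target_symbol
        )
        # block entries: (symbol, strand), target in the middle
        left: list[tuple[str, Strand]] = []
        right: list[tuple[str, Strand]] = []
        for ci, con in enumerate(pattern.constraints):
            entry = (
                con.anchor_symbol,
                _anchor_strand(target_strand, con.relative_orientation, rng),
            )
            if con.anchor_symbol.upper() in ablated:
                continue
            (left if ci % 2 == 0 else right).append(entry)
        block = (
            [e for e in reversed(left)]
            + [(target_symbol, target_strand)]
            + right
        )
        target_block_idx = len(left)

        decoy_order = list(truth.decoy_symbols)
        rng.shuffle(decoy_order)
        insert_at = int(rng.integers(0, len(decoy_order) + 1))
        entries: list[tuple[str, Strand, bool]] = []
        for i, d in enumerate(decoy_order):
            if i == insert_at:
                entries.extend((s, st, True) for s, st in block)
            entries.append(
                (d, Strand.FORWARD if rng.integers(2) == 0 else Strand.REVERSE, False)
            )
        if insert_at == len(decoy_order):
            entries.extend((s, st, True) for s, st in block)

        pos = 1
        gene_n = 0
        target_record: GeneRecord | None = None
        for sym, strand, in_block in entries:
            gap = int(rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1))
            length = int(
                rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1)
            )
            start = pos + gap
            end = start + length - 1
            if end > spec.scaffold_length_bp:
                raise ValueError(
                    "planted arrangement does not fit on the scaffold: "
                    f"needs > {spec.scaffold_length_bp} bp"
                )
            gene_n += 1
            rec = GeneRecord(
                gene_id=f"{species}_g{gene_n:03d}",
                symbol=sym,
                seq_id=seq_id,
                start=start,
                end=end,
                strand=strand,
                biotype="protein_coding",
                source="synthetic",
            )
            ann.add_gene(rec)
            if in_block and sym == target_symbol:
                target_record = rec
            pos = end
        assert target_record is not None
        panel.append(ann)
        truth.target_locus[species] = TargetLocus(
            seq_id=seq_id,
            start=target_record.start,
            end=target_record.end,
            strand=target_record.strand.value,
            symbol=target_symbol,
        )
        truth.constraint_satisfaction[species] = {
            con.anchor_symbol: con.anchor_symbol.upper() not in ablated
            for con in pattern.constraints
        }
    return panel, truth


def mirror_annotation(ann: AnnotationSet, scaffold_length: int) -> AnnotationSet:
    """Reverse-complement view of every scaffold: coordinates mirrored,
    strands flipped.  Used to test strand-flip invariance."""
    out = AnnotationSet(species=ann.species, assembly=ann.assembly)
    for g in ann:
        out.add_gene(
            GeneRecord(
                gene_id=g.gene_id,
                symbol=g.symbol,
                seq_id=g.seq_id,
                start=scaffold_length - g.end + 1,
                end=scaffold_length - g.start + 1,
                strand=g.strand.flipped(),
                biotype=g.biotype,
                source=g.source,
            )
        )
    return out


def generate_gc_cds(length: int, gc_target: float, seed: int = 0) -> str:
    """A sequence of exactly round(length * gc_target) G/C bases, shuffled.

    Composition is fixed (sample a composition, then shuffle), so the
    realised GC fraction deviates from the target only by integer
    rounding."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc_target <= 1.0):
        raise ValueError("gc_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_gc = round(length * gc_target)
    bases = np.concatenate(
        [
            rng.choice(np.array(list("GC")), size=n_gc),
            rng.choice(np.array(list("AT")), size=length - n_gc),
        ]
    )
    rng.shuffle(bases)
    return "".join(bases)


def generate_transcript_variant(
    reference_exons: Sequence[str],
    drop_set: Sequence[int],
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[str, dict]:
    """cDNA built by concatenating retained exons 5'->3' with iid
    substitution errors at ``error_rate``.

    ``drop_set`` holds 1-based exon indices (5'->3').  Dropping every exon
    is an error."""
    drop = set(drop_set)
    if not drop.issubset(range(1, len(reference_exons) + 1)):
        raise ValueError("drop_set contains out-of-range exon indices")
    if len(drop) == len(reference_exons):
        raise ValueError("cannot drop all exons")
    rng = np.random.default_rng(seed)
    kept = [
        e.upper() for i, e in enumerate(reference_exons, start=1) if i not in drop
    ]
    seq = list("".join(kept))
    n_errors = 0
    if error_rate > 0:
        alt = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
        hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
        for i in hits:
            base = seq[i]
            if base in alt:
                seq[i] = alt[base][rng.integers(3)]
                n_errors += 1
    truth = {
        "dropped_exons": sorted(drop),
        "n_exons_retained": len(kept),
        "n_substitutions": n_errors,
    }
    return "".join(seq), truth


def plant_domains(
    protein_length: int,
    plants: Sequence[tuple[str, int]],
    seed: int = 0,
) -> tuple[str, dict]:
    """Protein of iid-uniform residues with consensus motifs embedded.

    ``plants`` is a list of (consensus_sequence, 1-based position).
    Overlapping plants or plants running off the end are errors."""
    from .domains import AA_ALPHABET

    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    spans = []
    for consensus, position in plants:
        if position < 1 or position + len(consensus) - 1 > protein_length:
            raise ValueError(
                f"plant at {position} (length {len(consensus)}) exceeds protein "
                f"length {protein_length}"
            )
        spans.append((position, position + len(consensus) - 1))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("planted motifs overlap")
    rng = np.random.default_rng(seed)
    residues = list(
        "".join(rng.choice(np.array(list(AA_ALPHABET)), size=protein_length))
    )
    for consensus, position in plants:
        residues[position - 1 : position - 1 + len(consensus)] = list(consensus)
    truth = {
        "planted": [
            {"consensus": c, "start": p, "end": p + len(c) - 1} for c, p in plants
        ]
    }
    return "".join(residues), truth


def plant_domain(
    protein_length: int, profile_consensus: str, position: int, seed: int = 0
) -> str:
    """Single-motif convenience wrapper around :func:`plant_domains`."""
    protein, _ = plant_domains(protein_length, [(profile_consensus, position)], seed)
    return protein


def random_protein(length: int, seed: int = 0) -> str:
    """iid-uniform background protein (the null for threshold calibration)."""
    from .domains import AA_ALPHABET

    rng = np.random.default_rng(seed)
    return "".join(rng.choice(np.array(list(AA_ALPHABET)), size=length))


def plant_primer_sites(
    pair,
    product_length: int,
    template_length: int,
    gc_target: float = 0.5,
    seed: int = 0,
) -> tuple[str, dict]:
    """Template with one forward site and one reverse site planted so the
    end-to-end amplicon spans exactly ``product_length`` bp."""
    from .gc_pcr import reverse_complement

    min_len = len(pair.forward) + len(pair.reverse)
    if product_length < min_len:
        raise ValueError(
            f"product_length {product_length} shorter than combined primers "
            f"({min_len} bp)"
        )
    if template_length < product_length:
        raise ValueError("template shorter than the requested product")
    rng = np.random.default_rng(seed)
    background = generate_gc_cds(template_length, gc_target, seed=int(rng.integers(2**31)))
    slack = template_length - product_length
    f_start = int(rng.integers(0, slack + 1))  # 0-based
    seq = list(background)
    seq[f_start : f_start + len(pair.forward)] = list(pair.forward)
    rc = reverse_complement(pair.reverse)
    r_end = f_start + product_length  # exclusive
    seq[r_end - len(rc) : r_end] = list(rc)
    truth = {
        "product_length": product_length,
        "forward_site": (f_start + 1, f_start + len(pair.forward)),
        "reverse_site": (r_end - len(rc) + 1, r_end),
    }
    return "".join(seq), truth


def write_panel(
    panel: Sequence[AnnotationSet],
    truth: GroundTruth,
    out_dir: "str | os.PathLike",
) -> None:
    """Write one GFF3 per species plus the ground-truth JSON."""
    from .annotation_io import write_gff3

    os.makedirs(out_dir, exist_ok=True)
    for ann in panel:
        write_gff3(ann, os.path.join(out_dir, f"{ann.species}.gff3"))
    with open(os.path.join(out_dir, "ground_truth.json"), "wt") as fh:
        fh.write(truth.to_json())
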