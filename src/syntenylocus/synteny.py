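"""Anchor-based synteny localization.

The idea: a gene that is missing or misannotated in one genome can be located
by the company it keeps.  From species where the target gene *is* annotated we
learn which anchor genes sit within a small gene-order window of it and with
what relative orientation (microsynteny).  In a query genome the anchors are
found by symbol, and every gene (or empty slot) adjacent to them is scored by
how many learned constraints it satisfies.  For the pig ASMT case the learned
pattern is "AKAP17A adjacent, same orientation; ASMTL adjacent, opposite
orientation", which pinpoints the placeholder gene LOC110258194.

Adjacency is rank-based (positions in the coordinate-ordered, biotype-filtered
gene list), not bp-based, so it is robust to intergenic-length variation.
Relative orientation is strand-to-strand: ``same`` iff the two genes lie on
the same strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .models import AnnotationSet, GeneRecord, Strand

log = logging.getLogger(__name__)

SAME = "same"
OPPOSITE = "opposite"
ANY = "any"

DEFAULT_BIOTYPES = ("protein_coding",)


@dataclass(frozen=True)
class Neighbor:
    gene: GeneRecord
    rank: int  # signed offset in gene order; never 0
    relative_orientation: str  # same | opposite
    gap_bp: int  # non-negative bp gap between the two gene bodies


@dataclass(frozen=True)
class NeighborContext:
    """The k-nearest gene-order neighbourhood of one focal gene."""

    focal: GeneRecord
    neighbors: tuple[Neighbor, ...]

    def neighbor_by_symbol(self, symbol: str) -> "Neighbor | None":
        """Closest-rank neighbour carrying ``symbol`` (case-insensitive)."""
        hits = [n for n in self.neighbors if n.gene.symbol.upper() == symbol.upper()]
        if not hits:
            return None
        return min(hits, key=lambda n: (abs(n.rank), n.rank))


@dataclass(frozen=True)
class AnchorConstraint:
    """One learned adjacency/orientation rule for an anchor gene."""

    anchor_symbol: str
    max_rank: int
    relative_orientation: str  # same | opposite | any
    support: float
    supporting_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.relative_orientation not in (SAME, OPPOSITE, ANY):
            raise ValueError(f"bad orientation {self.relative_orientation!r}")
        if not (0.0 <= self.support <= 1.0):
            raise ValueError(f"support {self.support} outside [0,1]")
        if self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")

    def orientation_ok(self, candidate: GeneRecord, anchor: GeneRecord) -> bool:
        if self.relative_orientation == ANY:
            return True
        rel = SAME if candidate.strand == anchor.strand else OPPOSITE
        return rel == self.relative_orientation


@dataclass(frozen=True)
class SyntenyPattern:
    target_symbol: str
    constraints: tuple[AnchorConstraint, ...]
    min_support_used: float = 0.0

    def __post_init__(self) -> None:
        if not self.constraints:
            raise ValueError("SyntenyPattern requires at least one constraint")
        for c in self.constraints:
            if c.support < self.min_support_used:
                raise ValueError(
                    f"constraint {c.anchor_symbol}: support {c.support} below "
                    f"min_support_used {self.min_support_used}"
                )

    @property
    def anchor_symbols(self) -> tuple[str, ...]:
        return tuple(c.anchor_symbol for c in self.constraints)


@dataclass(frozen=True)
class LocusPrediction:
    """A candidate locus for the target gene in the query genome."""

    seq_id: str
    start: int
    end: int
    strand: "Strand | None"
    candidate_gene_id: "str | None"
    candidate_symbol: "str | None"
    satisfied: tuple[int, ...]  # indices into pattern.constraints
    score: int
    anchor_distance_bp: int  # summed bp gap to satisfied anchors (tie-break)
    rank: int = 0


class AnchorsNotFoundError(ValueError):
    """No anchor of the pattern is annotated in the query genome."""


class NoConsensusError(ValueError):
    """No anchor symbol reached the requested support."""


def extract_context(
    annotation: AnnotationSet,
    symbol: str,
    k: int = 2,
    biotypes: "Sequence[str] | None" = DEFAULT_BIOTYPES,
) -> list[NeighborContext]:
    """Neighbourhoods of every occurrence of ``symbol`` in ``annotation``.

    ``k`` is the window: the k nearest genes on each side in coordinate
    order on the same scaffold.  The biotype filter (default: protein-coding
    only) is applied before ranking, so small RNAs and pseudogenes do not
    consume rank positions.  An absent symbol yields an empty list.
    """
    if k < 1:
        raise ValueError("window k must be >= 1")
    contexts: list[NeighborContext] = []
    for focal in annotation.genes_by_symbol(symbol):
        order = annotation.ordered_genes(focal.seq_id, biotypes=biotypes)
        ids = [g.gene_id for g in order]
        if focal.gene_id not in ids:
            # focal filtered out by biotype; rank it against the filtered list
            order = sorted(
                order + [focal], key=lambda g: (g.start, g.end, g.gene_id)
            )
            ids = [g.gene_id for g in order]
        i = ids.index(focal.gene_id)
        neighbors = []
        for j in range(max(0, i - k), min(len(order), i + k + 1)):
            if j == i:
                continue
            other = order[j]
            rel = SAME if other.strand == focal.strand else OPPOSITE
            gap = max(
                0,
                max(focal.start, other.start) - min(focal.end, other.end) - 1,
            )
            neighbors.append(
                Neighbor(
                    gene=other,
                    rank=j - i,
                    relative_orientation=rel,
                    gap_bp=gap,
                )
            )
        contexts.append(NeighborContext(focal=focal, neighbors=tuple(neighbors)))
    return contexts


def build_consensus(
    contexts_by_species: Mapping[str, NeighborContext],
    target_symbol: str,
    candidate_anchors: "Iterable[str] | None" = None,
    min_support: float = 0.8,
    k: int = 2,
    annotations_by_species: "Mapping[str, AnnotationSet] | None" = None,
) -> SyntenyPattern:
    """Aggregate per-species neighbourhoods into a cross-species pattern.

    For every symbol appearing within the window in at least ``min_support``
    of informative species, emit an :class:`AnchorConstraint` with the
    majority relative orientation (ties -> ``any``) and the empirical
    support.  The support denominator for a symbol is the number of species
    where both target and anchor are annotated; without
    ``annotations_by_species`` this falls back to the number of species
    contributing a context.

    Aggregation is deterministic and independent of species input order.
    """
    if not contexts_by_species:
        raise ValueError("need at least one species context")
    if not (0.0 < min_support <= 1.0):
        raise ValueError("min_support must be in (0, 1]")

    species_sorted = sorted(contexts_by_species)
    wanted = (
        {s.upper() for s in candidate_anchors} if candidate_anchors is not None else None
    )

    # symbol -> species -> (closest rank, orientation)
    seen: dict[str, dict[str, Neighbor]] = {}
    for sp in species_sorted:
        ctx = contexts_by_species[sp]
        for nb in ctx.neighbors:
            sym = nb.gene.symbol.upper()
            if sym == target_symbol.upper():
                continue
            if wanted is not None and sym not in wanted:
                continue
            if abs(nb.rank) > k:
                continue
            cur = seen.setdefault(sym, {})
            if sp not in cur or abs(nb.rank) < abs(cur[sp].rank):
                cur[sp] = nb

    constraints: list[AnchorConstraint] = []
    best = (0.0, None)
    for sym in sorted(seen):
        per_species = seen[sym]
        if annotations_by_species is not None:
            denom = sum(
                1
                for sp in species_sorted
                if sp in annotations_by_species
                and annotations_by_species[sp].has_symbol(sym)
            )
        else:
            denom = len(species_sorted)
        if denom == 0:
            continue
        n_same = sum(
            1 for nb in per_species.values() if nb.relative_orientation == SAME
        )
        n_opp = len(per_species) - n_same
        if n_same > n_opp:
            orientation, n_consistent = SAME, n_same
        elif n_opp > n_same:
            orientation, n_consistent = OPPOSITE, n_opp
        else:
            orientation, n_consistent = ANY, len(per_species)
        support = n_consistent / denom
        supporting = tuple(
            sp
            for sp in sorted(per_species)
            if orientation == ANY
            or per_species[sp].relative_orientation == orientation
        )
        if support > best[0]:
            best = (support, sym)
        if support >= min_support:
            max_rank = max(abs(per_species[sp].rank) for sp in supporting)
            constraints.append(
                AnchorConstraint(
                    anchor_symbol=sym,
                    max_rank=max_rank,
                    relative_orientation=orientation,
                    support=support,
                    supporting_species=supporting,
                )
            )

    if not constraints:
        raise NoConsensusError(
            f"no anchor reached support {min_support}; best was "
            f"{best[1]!r} at {best[0]:.3f}"
        )
    return SyntenyPattern(
        target_symbol=target_symbol,
        constraints=tuple(constraints),
        min_support_used=min_support,
    )


def _satisfied_constraints(
    idx: int,
    order: list[GeneRecord],
    pattern: SyntenyPattern,
    anchor_positions: dict[str, list[int]],
) -> tuple[tuple[int, ...], int]:
    """Constraint indices satisfied by the gene at ``idx`` plus summed bp
    distance to the nearest satisfying occurrence of each anchor."""
    cand = order[idx]
    satisfied: list[int] = []
    total_gap = 0
    for ci, con in enumerate(pattern.constraints):
        best_gap: "int | None" = None
        for aj in anchor_positions.get(con.anchor_symbol.upper(), []):
            if aj == idx or abs(aj - idx) > con.max_rank:
                continue
            anchor = order[aj]
            if not con.orientation_ok(cand, anchor):
                continue
            gap = max(
                0, max(cand.start, anchor.start) - min(cand.end, anchor.end) - 1
            )
            if best_gap is None or gap < best_gap:
                best_gap = gap
        if best_gap is not None:
            satisfied.append(ci)
            total_gap += best_gap
    return tuple(satisfied), total_gap


def localize(
    query: AnnotationSet,
    pattern: SyntenyPattern,
    biotypes: "Sequence[str] | None" = DEFAULT_BIOTYPES,
    max_predictions: "int | None" = 20,
) -> list[LocusPrediction]:
    """Rank candidate loci for the pattern's target in a query genome.

    Every gene within an anchor's window is scored by the number of
    constraints it satisfies; if two anchors are immediately adjacent with
    no gene between them, the empty inter-anchor interval is also reported,
    with strand inferred from the orientation constraints.  Output is
    sorted by (score desc, summed bp distance to satisfied anchors asc,
    seq_id, start) — deterministic.
    """
    missing = [s for s in pattern.anchor_symbols if not query.has_symbol(s)]
    if len(missing) == len(pattern.constraints):
        raise AnchorsNotFoundError(
            f"none of the pattern anchors {list(pattern.anchor_symbols)} are "
            f"annotated in query {query.species!r}"
        )
    if missing:
        log.info("anchors missing from query (constraints unsatisfiable): %s", missing)

    preds: list[LocusPrediction] = []
    for seq_id in query.seq_ids:
        order = query.ordered_genes(seq_id, biotypes=biotypes)
        anchor_positions: dict[str, list[int]] = {}
        for i, g in enumerate(order):
            sym = g.symbol.upper()
            if sym in {s.upper() for s in pattern.anchor_symbols}:
                anchor_positions.setdefault(sym, []).append(i)
        if not anchor_positions:
            continue

        window = max(c.max_rank for c in pattern.constraints)
        candidate_idx = sorted(
            {
                j
                for positions in anchor_positions.values()
                for aj in positions
                for j in range(aj - window, aj + window + 1)
                if 0 <= j < len(order) and j != aj
            }
        )
        for j in candidate_idx:
            satisfied, gap = _satisfied_constraints(j, order, pattern, anchor_positions)
            if not satisfied:
                continue
            g = order[j]
            preds.append(
                LocusPrediction(
                    seq_id=seq_id,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    candidate_gene_id=g.gene_id,
                    candidate_symbol=g.symbol,
                    satisfied=satisfied,
                    score=len(satisfied),
                    anchor_distance_bp=gap,
                )
            )

        # empty-slot predictions: adjacent anchor pairs with a gap between
        flat_anchor_idx = sorted(
            {i for positions in anchor_positions.values() for i in positions}
        )
        for a, b in zip(flat_anchor_idx, flat_anchor_idx[1:]):
            if b - a != 1:
                continue
            left, right = order[a], order[b]
            if right.start - left.end <= 1:
                continue
            sat: list[int] = []
            strand_votes: list[Strand] = []
            total_gap = 0
            for ci, con in enumerate(pattern.constraints):
                for anchor in (left, right):
                    if anchor.symbol.upper() != con.anchor_symbol.upper():
                        continue
                    sat.append(ci)
                    total_gap += 0
                    if con.relative_orientation == SAME:
                        strand_votes.append(anchor.strand)
                    elif con.relative_orientation == OPPOSITE:
                        strand_votes.append(anchor.strand.flipped())
                    break
            if not sat:
                continue
            strand: "Strand | None" = None
            if strand_votes:
                n_fwd = sum(1 for s in strand_votes if s is Strand.FORWARD)
                if n_fwd * 2 != len(strand_votes):
                    strand = (
                        Strand.FORWARD
                        if n_fwd * 2 > len(strand_votes)
                        else Strand.REVERSE
                    )
            preds.append(
                LocusPrediction(
                    seq_id=seq_id,
                    start=left.end + 1,
                    end=right.start - 1,
                    strand=strand,
                    candidate_gene_id=None,
                    candidate_symbol=None,
                    satisfied=tuple(sorted(set(sat))),
                    score=len(set(sat)),
                    anchor_distance_bp=total_gap,
                )
            )

    if not preds:
        return []
    preds.sort(key=lambda p: (-p.score, p.anchor_distance_bp, p.seq_id, p.start))
    if max_predictions is not None:
        preds = preds[:max_predictions]
    return [
        LocusPrediction(**{**p.__dict__, "rank": i + 1}) for i, p in enumerate(preds)
    ]


def learn_pattern(
    panel: "Mapping[str, AnnotationSet] | Iterable[AnnotationSet]",
    target_symbol: str,
    candidate_anchors: "Iterable[str] | None" = None,
    min_support: float = 0.8,
    k: int = 2,
    biotypes: "Sequence[str] | None" = DEFAULT_BIOTYPES,
) -> SyntenyPattern:
    """Convenience wrapper: extract contexts across a species panel and
    build the consensus pattern for ``target_symbol``."""
    if not isinstance(panel, Mapping):
        panel = {a.species: a for a in panel}
    contexts: dict[str, NeighborContext] = {}
    for sp in sorted(panel):
        ctxs = extract_context(panel[sp], target_symbol, k=k, biotypes=biotypes)
        if ctxs:
            contexts[sp] = ctxs[0]
    if not contexts:
        raise ValueError(
            f"target symbol {target_symbol!r} not annotated in any panel species"
        )
    return build_consensus(
        contexts,
        target_symbol=target_symbol,
        candidate_anchors=candidate_anchors,
        min_support=min_support,
        k=k,
        annotations_by_species=dict(panel),
    )
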