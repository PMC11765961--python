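"""Agreement between two gene models for the same locus.

Used to show that independent annotations of one locus (e.g. an NCBI
placeholder gene and an Ensembl stable-ID gene) describe the same exon
structure.  Comparison is positional: exonic base sets over 1-based
inclusive intervals, no CDS-phase awareness.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import ExonChain


@dataclass(frozen=True)
class ExonConcordance:
    base_jaccard: float  # |intersection| / |union| of exonic base sets
    exact_exon_matches: int  # exons identical (same start and end) in both
    a_only: int  # exons of a with no exact counterpart in b
    b_only: int
    identical: bool

    def swapped(self) -> "ExonConcordance":
        return ExonConcordance(
            base_jaccard=self.base_jaccard,
            exact_exon_matches=self.exact_exon_matches,
            a_only=self.b_only,
            b_only=self.a_only,
            identical=self.identical,
        )


def _intersection_bp(a: tuple[tuple[int, int], ...], b: tuple[tuple[int, int], ...]) -> int:
    """Total overlap between two sorted, internally disjoint interval lists."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            total += e - s + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def compare_exon_chains(a: ExonChain, b: ExonChain) -> ExonConcordance:
    """Positional concordance of two exon chains on the same scaffold/strand.

    Chains on different scaffolds or strands are an error rather than a
    silent zero: such a comparison is a caller mistake, not a discordance.
    """
    if a.seq_id != b.seq_id:
        raise ValueError(f"exon chains on different scaffolds: {a.seq_id!r} vs {b.seq_id!r}")
    if a.strand != b.strand:
        raise ValueError(
            f"exon chains on different strands: {a.strand.value} vs {b.strand.value}"
        )
    len_a = sum(e - s + 1 for s, e in a.exons)
    len_b = sum(e - s + 1 for s, e in b.exons)
    inter = _intersection_bp(a.exons, b.exons)
    union = len_a + len_b - inter
    jaccard = inter / union if union else 0.0

    set_a = set(a.exons)
    set_b = set(b.exons)
    exact = len(set_a & set_b)
    a_only = len(a.exons) - exact
    b_only = len(b.exons) - exact
    return ExonConcordance(
        base_jaccard=jaccard,
        exact_exon_matches=exact,
        a_only=a_only,
        b_only=b_only,
        identical=(jaccard == 1.0 and a_only == 0 and b_only == 0),
    )


def best_transcript_pairing(
    chains_a: list[ExonChain], chains_b: list[ExonChain]
) -> list[tuple[str, str, ExonConcordance]]:
    """Greedy pairing of transcripts from two gene models by base overlap."""
    results = []
    used_b: set[str] = set()
    scored = []
    for ca in chains_a:
        for cb in chains_b:
            if ca.seq_id != cb.seq_id or ca.strand != cb.strand:
                continue
            scored.append((_intersection_bp(ca.exons, cb.exons), ca, cb))
    scored.sort(key=lambda t: (-t[0], t[1].transcript_id, t[2].transcript_id))
    used_a: set[str] = set()
    for _, ca, cb in scored:
        if ca.transcript_id in used_a or cb.transcript_id in used_b:
            continue
        used_a.add(ca.transcript_id)
        used_b.add(cb.transcript_id)
        results.append((ca.transcript_id, cb.transcript_id, compare_exon_chains(ca, cb)))
    return results
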