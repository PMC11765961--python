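"""Exon-level mapping of a cloned cDNA onto a reference gene model.

A Sanger-cloned cDNA is matched against the ordered exon sequences of a
reference transcript; exons that fail to match signal an exon-skipping
transcript variant (the way a new six-exon ASMT transcript was recognised
from an eight-exon reference).  Variants are then compared across species by
their missing-exon signature.

Matching is per-exon, ungapped and colinear — deliberately not a spliced
genome aligner: the evidence sought is exon-block presence/absence, and a
~1% Sanger error rate is absorbed by a per-exon identity threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.95
MIN_EXON_LENGTH = 10
MAX_CANDIDATES_PER_EXON = 20


@dataclass(frozen=True)
class ExonMatch:
    exon_index: int  # 1-based, 5'->3' on the transcript
    matched: bool
    identity: float  # best full-length identity found in the query
    query_span: "tuple[int, int] | None"  # 1-based inclusive, if matched


@dataclass(frozen=True)
class SplicedMap:
    query_id: str
    reference_transcript_id: str
    exon_records: tuple[ExonMatch, ...]
    missing_exons: tuple[int, ...]  # 1-based indices, 5'->3'
    n_query_exons: int

    @property
    def reference_exon_count(self) -> int:
        return len(self.exon_records)

    @property
    def missing_exons_from_3p(self) -> tuple[int, ...]:
        """Missing exon indices counted from the 3' end (1 = last exon)."""
        n = self.reference_exon_count
        return tuple(sorted(n - i + 1 for i in self.missing_exons))


@dataclass(frozen=True)
class VariantSignature:
    reference_exon_count: int
    present_pattern: tuple[bool, ...]  # 5'->3'

    def __post_init__(self) -> None:
        if len(self.present_pattern) != self.reference_exon_count:
            raise ValueError("pattern length must equal reference_exon_count")

    @property
    def missing_from_3p(self) -> frozenset[int]:
        n = self.reference_exon_count
        return frozenset(
            n - i for i, present in enumerate(self.present_pattern) if not present
        )

    def as_string(self) -> str:
        return "".join("1" if p else "0" for p in self.present_pattern)


def _merge_short_exons(exons: list[str]) -> list[str]:
    """Merge exons shorter than MIN_EXON_LENGTH into the following exon
    (preceding exon for a trailing short exon); logged."""
    merged = list(exons)
    i = 0
    while i < len(merged):
        if len(merged[i]) < MIN_EXON_LENGTH and len(merged) > 1:
            if i + 1 < len(merged):
                log.warning(
                    "reference exon %d (%d bp) shorter than %d bp; merged with "
                    "the next exon", i + 1, len(merged[i]), MIN_EXON_LENGTH,
                )
                merged[i + 1] = merged[i] + merged[i + 1]
                del merged[i]
            else:
                log.warning(
                    "trailing reference exon %d (%d bp) shorter than %d bp; "
                    "merged with the previous exon",
                    i + 1, len(merged[i]), MIN_EXON_LENGTH,
                )
                merged[i - 1] = merged[i - 1] + merged[i]
                del merged[i]
        else:
            i += 1
    return merged


def _identity_profile(query_idx: np.ndarray, exon: str) -> np.ndarray:
    """Full-length identity of ``exon`` at every query offset (0-based)."""
    e = np.frombuffer(exon.encode(), dtype=np.uint8)
    L = len(e)
    if len(query_idx) < L:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(query_idx, L)
    return (windows == e).mean(axis=1)


def map_exons(
    query_cdna: str,
    reference_exon_sequences: list[str],
    query_id: str = "query",
    reference_transcript_id: str = "reference",
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> SplicedMap:
    """Locate each reference exon in the query and call missing exons.

    Each exon is matched by its best full-length ungapped placement; an exon
    counts as present iff identity >= ``identity_threshold``.  Matched
    placements must be colinear and non-overlapping in the query; when
    candidate placements conflict (e.g. duplicated exon sequences) the
    colinear assignment maximising total identity is chosen by dynamic
    programming, and exons squeezed out of any colinear chain are demoted to
    unmatched with a log message.
    """
    if not query_cdna:
        raise ValueError("empty query cDNA")
    if not reference_exon_sequences:
        raise ValueError("need at least one reference exon")
    exons = _merge_short_exons([e.upper() for e in reference_exon_sequences])
    query = query_cdna.upper()
    q = np.frombuffer(query.encode(), dtype=np.uint8)

    # candidate placements per exon: all offsets at/above threshold (capped),
    # plus the single best offset for reporting identity of unmatched exons
    candidates: list[list[tuple[int, float]]] = []
    best_identity: list[float] = []
    for exon in exons:
        prof = _identity_profile(q, exon)
        if prof.size == 0:
            candidates.append([])
            best_identity.append(0.0)
            continue
        best_identity.append(float(prof.max()))
        qualifying = np.nonzero(prof >= identity_threshold)[0]
        if qualifying.size > MAX_CANDIDATES_PER_EXON:
            keep = qualifying[np.argsort(-prof[qualifying])][:MAX_CANDIDATES_PER_EXON]
            qualifying = np.sort(keep)
        candidates.append([(int(o), float(prof[o])) for o in qualifying])

    # DP over exons: choose at most one placement per exon, spans strictly
    # colinear and non-overlapping; maximise (#matched, total identity)
    n = len(exons)
    flat: list[tuple[int, int, int, float]] = []  # (exon_i, start, end_excl, ident)
    for i, cand in enumerate(candidates):
        for off, ident in cand:
            flat.append((i, off, off + len(exons[i]), ident))
    # dp[j] = best (count, identity_sum, parent) ending with placement j
    m = len(flat)
    dp_count = [1] * m
    dp_ident = [flat[j][3] for j in range(m)]
    parent = [-1] * m
    order = sorted(range(m), key=lambda j: (flat[j][0], flat[j][1]))
    for a_pos, j in enumerate(order):
        ei, s, e, ident = flat[j]
        for k in order[:a_pos]:
            ek, sk, eke, _ = flat[k]
            if ek < ei and eke <= s:
                cand_count = dp_count[k] + 1
                cand_ident = dp_ident[k] + ident
                if (cand_count, cand_ident) > (dp_count[j], dp_ident[j]):
                    dp_count[j] = cand_count
                    dp_ident[j] = cand_ident
                    parent[j] = k
    chosen: dict[int, tuple[int, int, float]] = {}
    if m:
        j = max(range(m), key=lambda j: (dp_count[j], dp_ident[j]))
        while j != -1:
            ei, s, e, ident = flat[j]
            chosen[ei] = (s, e, ident)
            j = parent[j]
    demoted = [
        i + 1 for i in range(n) if candidates[i] and i not in chosen
    ]
    if demoted:
        log.warning(
            "exon(s) %s had above-threshold placements but no colinear slot; "
            "demoted to unmatched", demoted,
        )

    records = []
    for i in range(n):
        if i in chosen:
            s, e, ident = chosen[i]
            records.append(
                ExonMatch(
                    exon_index=i + 1,
                    matched=True,
                    identity=ident,
                    query_span=(s + 1, e),
                )
            )
        else:
            records.append(
                ExonMatch(
                    exon_index=i + 1,
                    matched=False,
                    identity=best_identity[i],
                    query_span=None,
                )
            )
    missing = tuple(r.exon_index for r in records if not r.matched)
    return SplicedMap(
        query_id=query_id,
        reference_transcript_id=reference_transcript_id,
        exon_records=tuple(records),
        missing_exons=missing,
        n_query_exons=sum(1 for r in records if r.matched),
    )


def signature(spliced_map: SplicedMap) -> VariantSignature:
    """Exon presence/absence bit-vector, 5'->3'."""
    return VariantSignature(
        reference_exon_count=spliced_map.reference_exon_count,
        present_pattern=tuple(r.matched for r in spliced_map.exon_records),
    )


def match_variants(sig_a: VariantSignature, sig_b: VariantSignature) -> str:
    """``corresponding`` iff the missing-exon sets, counted from the 3' end,
    are identical; else ``different``.

    The 3'-anchored comparison lets variants of references with different
    exon counts correspond (a nine-exon and a ten-exon reference both
    missing their last-but-one and last-but-two exons match).  Symmetric and
    total."""
    return (
        "corresponding" if sig_a.missing_from_3p == sig_b.missing_from_3p else "different"
    )
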