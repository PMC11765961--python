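"""Paralog disambiguation by protein-domain architecture.

ASMT and its paralog ASMTL share the Methyltransf_2 (O-methyltransferase)
domain; ASMTL additionally carries a Maf-like domain.  Presence/absence of
Maf therefore separates the two, which is exactly the decision this module
implements: an ungapped position-specific scoring matrix (PSSM) scan with an
empirically calibrated score threshold, followed by a three-way decision
table (both domains -> ASMTL, Methyltransf_2 only -> ASMT, otherwise
unclassified).

Scores are base-2 log-odds against a uniform residue background with +1
pseudocounts.  No indel states are modelled: the call is presence/absence,
not domain-boundary reconstruction.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

LABEL_ASMT = "ASMT"
LABEL_ASMTL = "ASMTL"
LABEL_UNCLASSIFIED = "unclassified"

MIN_PROFILE_LENGTH = 10
DEFAULT_TARGET_FPR = 0.001  # per 1000-aa background protein


@dataclass(frozen=True)
class DomainProfile:
    """Fixed-length log-odds profile for one protein domain."""

    name: str
    matrix: np.ndarray  # shape (L, 20), base-2 log-odds
    threshold: float
    provenance: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(AA_ALPHABET):
            raise ValueError(f"profile {self.name}: matrix must be L x 20")
        if m.shape[0] < MIN_PROFILE_LENGTH:
            raise ValueError(
                f"profile {self.name}: length {m.shape[0]} < {MIN_PROFILE_LENGTH}"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def with_threshold(self, threshold: float) -> "DomainProfile":
        return DomainProfile(self.name, self.matrix, float(threshold), self.provenance)


@dataclass(frozen=True)
class DomainHit:
    profile_name: str
    start: int  # 1-based inclusive on the protein
    end: int
    score: float


@dataclass(frozen=True)
class ParalogCall:
    label: str  # ASMT | ASMTL | unclassified
    evidence: tuple[DomainHit, ...]


def build_profile(
    name: str,
    aligned_sequences: Sequence[str],
    pseudocount: float = 1.0,
    provenance: str = "",
) -> DomainProfile:
    """Build a log-odds profile from an ungapped seed alignment.

    score(p, a) = log2( (count_pa + pseudocount) / (n + 20*pseudocount)
                        / (1/20) ).
    The threshold is left at half the maximum attainable score until
    :func:`calibrate_threshold` replaces it.
    """
    if not aligned_sequences:
        raise ValueError("need at least one aligned sequence")
    L = len(aligned_sequences[0])
    if any(len(s) != L for s in aligned_sequences):
        raise ValueError("seed sequences must be aligned (equal length)")
    counts = np.zeros((L, len(AA_ALPHABET)))
    for seq in aligned_sequences:
        for p, aa in enumerate(seq.upper()):
            if aa in _AA_INDEX:
                counts[p, _AA_INDEX[aa]] += 1
    n = len(aligned_sequences)
    freqs = (counts + pseudocount) / (n + len(AA_ALPHABET) * pseudocount)
    matrix = np.log2(freqs * len(AA_ALPHABET))
    prof = DomainProfile(name=name, matrix=matrix, threshold=0.0, provenance=provenance)
    return prof.with_threshold(prof.max_score / 2.0)


def encode_protein(protein: str) -> np.ndarray:
    """Map residues to alphabet indices; non-standard residues -> -1."""
    return np.array([_AA_INDEX.get(aa, -1) for aa in protein.upper()], dtype=int)


def window_scores(protein: str, profile: DomainProfile) -> np.ndarray:
    """Summed log-odds of every length-L window (1-based starts 1..n-L+1).

    Non-standard residues contribute 0 (background)."""
    idx = encode_protein(protein)
    n, L = len(idx), profile.length
    if n < L:
        return np.zeros(0)
    # pad matrix with a zero column for non-standard residues
    padded = np.hstack([profile.matrix, np.zeros((L, 1))])
    scores = np.zeros(n - L + 1)
    for p in range(L):
        scores += padded[p, idx[p : p + n - L + 1]]
    return scores


def scan(protein: str, profile: DomainProfile) -> list[DomainHit]:
    """All above-threshold windows, overlapping hits merged keeping the
    maximum-score window.  A protein shorter than the profile yields an
    empty result with a warning."""
    if len(protein) < profile.length:
        log.warning(
            "protein length %d < profile %s length %d; no scan performed",
            len(protein), profile.name, profile.length,
        )
        return []
    scores = window_scores(protein, profile)
    above = np.nonzero(scores >= profile.threshold)[0]
    if above.size == 0:
        return []
    # greedy merge: accept windows by descending score, drop overlaps
    order = above[np.lexsort((above, -scores[above]))]
    taken: list[int] = []
    L = profile.length
    for i in order:
        if all(abs(i - j) >= L for j in taken):
            taken.append(int(i))
    hits = [
        DomainHit(
            profile_name=profile.name,
            start=i + 1,
            end=i + L,
            score=float(scores[i]),
        )
        for i in sorted(taken)
    ]
    return hits


def calibrate_threshold(
    profile: DomainProfile,
    background_sequences: Sequence[str],
    target_fpr: float = DEFAULT_TARGET_FPR,
) -> float:
    """Empirical (1 - target_fpr) quantile of per-sequence max window scores.

    ``target_fpr`` is the tolerated fraction of background proteins with at
    least one reported hit.  Requires >= 100 background sequences;
    deterministic for a fixed background set.
    """
    if len(background_sequences) < 100:
        raise ValueError(
            f"need >= 100 background sequences, got {len(background_sequences)}"
        )
    if not (0.0 <= target_fpr < 1.0):
        raise ValueError("target_fpr must be in [0, 1)")
    maxima = []
    for seq in background_sequences:
        ws = window_scores(seq, profile)
        if ws.size:
            maxima.append(float(ws.max()))
    if not maxima:
        raise ValueError("all background sequences shorter than the profile")
    arr = np.sort(np.asarray(maxima))
    if target_fpr == 0.0:
        return float(arr[-1]) + 1e-9  # strictly above every background score
    return float(np.quantile(arr, 1.0 - target_fpr, method="higher"))


def classify(
    protein: str,
    profiles: "dict[str, DomainProfile] | Iterable[DomainProfile]",
    methyltransferase_name: str = "Methyltransf_2",
    maf_name: str = "Maf",
) -> ParalogCall:
    """ASMT/ASMTL decision from domain presence.

    (Methyltransf_2 and Maf) -> ASMTL; (Methyltransf_2 only) -> ASMT;
    anything else -> unclassified.  Total and deterministic.
    """
    if not isinstance(profiles, dict):
        profiles = {p.name: p for p in profiles}
    for needed in (methyltransferase_name, maf_name):
        if needed not in profiles:
            raise KeyError(f"profile {needed!r} not supplied")
    mt_hits = scan(protein, profiles[methyltransferase_name])
    maf_hits = scan(protein, profiles[maf_name])
    evidence = tuple(mt_hits + maf_hits)
    if mt_hits and maf_hits:
        return ParalogCall(label=LABEL_ASMTL, evidence=evidence)
    if mt_hits:
        return ParalogCall(label=LABEL_ASMT, evidence=evidence)
    return ParalogCall(label=LABEL_UNCLASSIFIED, evidence=evidence)


# ---------------------------------------------------------------------------
# plain-text profile fixture format


def write_profile(profile: DomainProfile, stream: "str | os.PathLike | IO") -> None:
    """Serialise a profile as plain text (header lines + L rows of 20 scores)."""

    def _emit(out: IO) -> None:
        out.write(f"NAME\t{profile.name}\n")
        out.write(f"LENGTH\t{profile.length}\n")
        out.write(f"ALPHABET\t{AA_ALPHABET}\n")
        out.write(f"THRESHOLD\t{profile.threshold:.6f}\n")
        if profile.provenance:
            out.write(f"PROVENANCE\t{profile.provenance}\n")
        for row in profile.matrix:
            out.write("\t".join(f"{v:.6f}" for v in row) + "\n")

    if isinstance(stream, (str, os.PathLike)):
        with open(stream, "wt") as fh:
            _emit(fh)
    else:
        _emit(stream)


def read_profile(stream: "str | os.PathLike | IO") -> DomainProfile:
    if isinstance(stream, (str, os.PathLike)):
        with open(stream, "rt") as fh:
            text = fh.read()
    else:
        text = stream.read()
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] in ("NAME", "LENGTH", "ALPHABET", "THRESHOLD", "PROVENANCE"):
            meta[fields[0]] = fields[1]
        else:
            rows.append([float(v) for v in fields])
    if meta.get("ALPHABET", AA_ALPHABET) != AA_ALPHABET:
        raise ValueError("unsupported profile alphabet")
    matrix = np.asarray(rows)
    if matrix.shape[0] != int(meta["LENGTH"]):
        raise ValueError(
            f"profile {meta.get('NAME')}: row count {matrix.shape[0]} does not "
            f"match LENGTH {meta['LENGTH']}"
        )
    return DomainProfile(
        name=meta["NAME"],
        matrix=matrix,
        threshold=float(meta["THRESHOLD"]),
        provenance=meta.get("PROVENANCE", ""),
    )


def load_profile_dir(path: "str | os.PathLike") -> dict[str, DomainProfile]:
    """Load every ``*.pssm`` file in a directory, keyed by profile name."""
    profiles: dict[str, DomainProfile] = {}
    for fname in sorted(os.listdir(path)):
        if fname.endswith(".pssm"):
            prof = read_profile(os.path.join(path, fname))
            profiles[prof.name] = prof
    if not profiles:
        raise FileNotFoundError(f"no .pssm profiles found in {path}")
    return profiles


def bundled_profiles() -> dict[str, DomainProfile]:
    """The synthetic Methyltransf_2/Maf stand-in profiles shipped with the
    package (see data/profiles; built from synthetic seed alignments, not
    from curated domain databases)."""
    here = os.path.dirname(__file__)
    return load_profile_dir(os.path.join(here, "data", "profiles"))
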