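"""Cloning support: GC statistics, in-silico PCR and slow-down PCR programs.

GC-rich templates (the pig ASMT CDS runs at ~65% GC) resist standard PCR;
the slow-down program counters this with a stepwise touchdown: the annealing
temperature starts high and is decremented every few cycles, trading early
stringency for late yield.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from Bio.Seq import Seq

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrimerPair:
    """A named forward/reverse primer pair, both written 5'->3'.

    Degenerate IUPAC codes are rejected: amplicon prediction here is exact
    string matching, and mixed-base primers would silently inflate site
    counts."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            seq = seq.upper()
            if len(seq) < 10:
                raise ValueError(f"{self.name} {label} primer shorter than 10 nt")
            if not re.fullmatch(r"[ACGT]+", seq):
                raise ValueError(
                    f"{self.name} {label} primer contains non-ACGT (degenerate?) "
                    f"characters: {seq}"
                )
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class AmpliconReport:
    template_id: str
    forward_site: tuple[int, int]  # 1-based inclusive
    reverse_site: tuple[int, int]
    product_length: int
    product_gc: float  # percent

    def __post_init__(self) -> None:
        expected = self.reverse_site[1] - self.forward_site[0] + 1
        if self.product_length != expected or self.product_length <= 0:
            raise ValueError("inconsistent amplicon coordinates")


@dataclass(frozen=True)
class ThermalProgram:
    """A cycling program: blocks of (denaturation, annealing, extension)."""

    pre_denaturation: tuple[float, int]  # (temp C, seconds)
    blocks: tuple[tuple[tuple[float, int], tuple[float, int], tuple[float, int], int], ...]
    final_extension: tuple[float, int]

    @property
    def total_cycles(self) -> int:
        return sum(b[3] for b in self.blocks)

    @property
    def annealing_temps(self) -> list[float]:
        return [b[1][0] for b in self.blocks]

    def as_text(self) -> str:
        """Render as a bench-protocol block."""

        def fmt(t: float) -> str:
            return f"{t:g}"

        lines = [
            f"Pre-denaturation at {fmt(self.pre_denaturation[0])} °C for "
            f"{self.pre_denaturation[1]} s."
        ]
        for denat, anneal, extend, cycles in self.blocks:
            lines.append(
                f"{fmt(denat[0])} °C {denat[1]} s, {fmt(anneal[0])} °C {anneal[1]} s, "
                f"{fmt(extend[0])} °C {extend[1]} s, {cycles} cycles;"
            )
        lines.append(
            f"Final extension at {fmt(self.final_extension[0])} °C for "
            f"{self.final_extension[1]} s."
        )
        return "\n".join(lines)


def gc_content(sequence: str) -> float:
    """GC percentage over unambiguous bases.

    Non-ACGT characters are excluded from both numerator and denominator; a
    warning is logged if they exceed 1% of the input."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    counts = {c: seq.count(c) for c in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    ambiguous = len(seq) - denom
    if ambiguous / len(seq) > 0.01:
        log.warning(
            "%.1f%% of bases are ambiguous and excluded from GC computation",
            100 * ambiguous / len(seq),
        )
    return 100.0 * (counts["G"] + counts["C"]) / denom


def gc_sliding(sequence: str, window: int, step: int) -> list[tuple[int, float]]:
    """Per-window GC along the sequence.

    Windows start at 1-based offsets 1, 1+step, 1+2*step, ...; a trailing
    partial window is reported iff it is at least half the window long."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    seq = sequence.upper()
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    out: list[tuple[int, float]] = []
    pos = 0
    while pos < len(seq):
        chunk = seq[pos : pos + window]
        if len(chunk) < window and len(chunk) < window / 2:
            break
        out.append((pos + 1, gc_content(chunk)))
        if pos + window >= len(seq):
            break
        pos += step
    return out


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence.upper()).reverse_complement())


def _match_sites(template: str, primer: str, max_mismatches: int, protect_3p_left: bool) -> list[int]:
    """0-based start offsets where ``primer`` matches ``template``.

    With mismatches allowed, the 3 primer bases at the 3' terminus must
    still match exactly (3' mismatches abolish polymerase extension).  For a
    plus-strand primer the 3' end is the right end; for a reverse primer
    matched as its reverse complement the 3' end maps to the left end of the
    site (``protect_3p_left=True``)."""
    m = len(primer)
    sites = []
    if max_mismatches == 0:
        start = template.find(primer)
        while start != -1:
            sites.append(start)
            start = template.find(primer, start + 1)
        return sites
    protected = range(0, 3) if protect_3p_left else range(m - 3, m)
    for start in range(len(template) - m + 1):
        mism = 0
        ok = True
        for i in range(m):
            if template[start + i] != primer[i]:
                if i in protected:
                    ok = False
                    break
                mism += 1
                if mism > max_mismatches:
                    ok = False
                    break
        if ok:
            sites.append(start)
    return sites


def insilico_pcr(
    template: str,
    pair: PrimerPair,
    template_id: str = "template",
    max_mismatches: int = 0,
) -> list[AmpliconReport]:
    """Predict amplicons of ``pair`` on ``template`` (plus strand).

    The forward primer is matched directly; the reverse primer is matched as
    its reverse complement downstream of the forward site.  Every compatible
    site pair is reported (no silent choice among multiple sites), sorted by
    product length.  Product length is end-to-end, both primer footprints
    included."""
    seq = template.upper()
    if len(seq) < len(pair.forward) + len(pair.reverse):
        raise ValueError("template shorter than the combined primer lengths")
    fwd_sites = _match_sites(seq, pair.forward, max_mismatches, protect_3p_left=False)
    rev_rc = reverse_complement(pair.reverse)
    rev_sites = _match_sites(seq, rev_rc, max_mismatches, protect_3p_left=True)
    reports = []
    for f in fwd_sites:
        f_end = f + len(pair.forward)  # exclusive
        for r in rev_sites:
            if r < f_end:
                continue
            r_end = r + len(rev_rc)
            product = seq[f:r_end]
            reports.append(
                AmpliconReport(
                    template_id=template_id,
                    forward_site=(f + 1, f_end),
                    reverse_site=(r + 1, r_end),
                    product_length=len(product),
                    product_gc=gc_content(product),
                )
            )
    reports.sort(key=lambda a: (a.product_length, a.forward_site))
    return reports


def slowdown_program(
    anneal_start: float = 72,
    anneal_end: float = 65,
    decrement: float = 1,
    cycles_per_block: int = 4,
    denat: tuple[float, int] = (98, 10),
    anneal_seconds: int = 30,
    extend: tuple[float, int] = (72, 45),
    pre_denat: tuple[float, int] = (98, 120),
    final_ext: tuple[float, int] = (72, 600),
) -> ThermalProgram:
    """Stepwise touchdown ("slow-down") cycling program.

    Annealing blocks run at anneal_start, anneal_start - decrement, ...,
    anneal_end, each for ``cycles_per_block`` cycles.  The defaults
    reproduce the 72->65 °C, 4-cycles-per-degree program used to amplify
    the GC-rich ASMT coding region."""
    if anneal_start < anneal_end:
        raise ValueError("anneal_start must be >= anneal_end")
    if decrement <= 0:
        raise ValueError("decrement must be positive")
    if cycles_per_block <= 0:
        raise ValueError("cycles_per_block must be positive")
    span = anneal_start - anneal_end
    n_steps = round(span / decrement)
    if abs(n_steps * decrement - span) > 1e-9:
        raise ValueError(
            f"decrement {decrement} does not evenly divide the annealing span "
            f"{anneal_start}-{anneal_end}"
        )
    blocks = tuple(
        (
            denat,
            (anneal_start - i * decrement, anneal_seconds),
            extend,
            cycles_per_block,
        )
        for i in range(int(n_steps) + 1)
    )
    return ThermalProgram(
        pre_denaturation=pre_denat, blocks=blocks, final_extension=final_ext
    )
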