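"""End-to-end orchestration: localize -> classify -> concordance -> cloning
support -> transcript-variant call.

A run is described by a flat key-value config file with sections
(:mod:`configparser` syntax); each section enables one stage.  Outputs are
TSV/text files in the configured output directory plus a run log recording
versions, seed and the full parameter echo, so a run can be reproduced from
its log alone.
"""

from __future__ import annotations

import configparser
import dataclasses
import io
import logging
import os
import sys
from dataclasses import dataclass, field
from typing import Mapping

from . import __version__
from .annotation_io import read_fasta, read_gff3
from .concordance import best_transcript_pairing
from .domains import classify, load_profile_dir
from .gc_pcr import PrimerPair, gc_content, gc_sliding, insilico_pcr, slowdown_program
from .synteny import learn_pattern, localize
from .transcripts import map_exons, signature

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parsed run configuration.  All paths must exist at run time."""

    out_dir: str
    seed: int = 0
    sections: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: "str | os.PathLike") -> "RunConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(path)
        sections = {s: dict(parser[s]) for s in parser.sections()}
        run = sections.pop("run", {})
        return cls(
            out_dir=run.get("out_dir", "syntenylocus_out"),
            seed=int(run.get("seed", "0")),
            sections=sections,
        )

    def to_file(self, path: "str | os.PathLike") -> None:
        parser = configparser.ConfigParser()
        parser["run"] = {"out_dir": self.out_dir, "seed": str(self.seed)}
        for name, kv in self.sections.items():
            parser[name] = dict(kv)
        with open(path, "wt") as fh:
            parser.write(fh)


def _parse_primer_pairs(raw: str) -> list[PrimerPair]:
    """Parse ``name:FWD:REV`` entries separated by commas or whitespace."""
    pairs = []
    for chunk in raw.replace(",", " ").split():
        name, fwd, rev = chunk.split(":")
        pairs.append(PrimerPair(name=name, forward=fwd, reverse=rev))
    if not pairs:
        raise ValueError("no primer pairs configured")
    return pairs


def _stage_localize(cfg: Mapping[str, str], out_dir: str, report: list[str]) -> None:
    panel_dir = cfg["panel_dir"]
    panel = []
    for fname in sorted(os.listdir(panel_dir)):
        if fname.endswith((".gff3", ".gff")):
            panel.append(
                read_gff3(
                    os.path.join(panel_dir, fname),
                    source_label="other",
                    species=os.path.splitext(fname)[0],
                )
            )
    query = read_gff3(cfg["query"], source_label="other", species="query")
    anchors = cfg.get("anchors")
    pattern = learn_pattern(
        panel,
        target_symbol=cfg["target"],
        candidate_anchors=anchors.split(",") if anchors else None,
        min_support=float(cfg.get("min_support", "0.8")),
        k=int(cfg.get("window", "2")),
    )
    preds = localize(query, pattern)
    out = os.path.join(out_dir, "predictions.tsv")
    with open(out, "wt") as fh:
        fh.write(
            "rank\tseq_id\tstart\tend\tstrand\tcandidate_gene_id\t"
            "candidate_symbol\tscore\tsatisfied\tanchor_distance_bp\n"
        )
        for p in preds:
            fh.write(
                f"{p.rank}\t{p.seq_id}\t{p.start}\t{p.end}\t"
                f"{p.strand.value if p.strand else '.'}\t"
                f"{p.candidate_gene_id or '.'}\t{p.candidate_symbol or '.'}\t"
                f"{p.score}\t{','.join(map(str, p.satisfied))}\t"
                f"{p.anchor_distance_bp}\n"
            )
    report.append(
        f"localize: pattern anchors {list(pattern.anchor_symbols)}; "
        f"{len(preds)} prediction(s); top candidate "
        f"{preds[0].candidate_symbol if preds else 'none'}"
    )


def _stage_classify(cfg: Mapping[str, str], out_dir: str, report: list[str]) -> None:
    proteins = read_fasta(cfg["protein_fasta"])
    profiles = load_profile_dir(cfg["profile_dir"])
    out = os.path.join(out_dir, "calls.tsv")
    with open(out, "wt") as fh:
        fh.write("protein_id\tlabel\tevidence\n")
        for pid in sorted(proteins):
            call = classify(proteins[pid], profiles)
            ev = ";".join(
                f"{h.profile_name}:{h.start}-{h.end}:{h.score:.1f}"
                for h in call.evidence
            )
            fh.write(f"{pid}\t{call.label}\t{ev or '.'}\n")
            report.append(f"classify: {pid} -> {call.label}")


def _stage_concord(cfg: Mapping[str, str], out_dir: str, report: list[str]) -> None:
    ann_a = read_gff3(cfg["gff_a"], source_label="ncbi", species="a")
    ann_b = read_gff3(cfg["gff_b"], source_label="ensembl", species="b")
    genes_a = ann_a.genes_by_symbol(cfg["gene_a"])
    genes_b = ann_b.genes_by_symbol(cfg["gene_b"])
    if not genes_a or not genes_b:
        raise ValueError("configured gene symbols not found in the inputs")
    chains_a = ann_a.transcripts_of(genes_a[0].gene_id)
    chains_b = ann_b.transcripts_of(genes_b[0].gene_id)
    pairs = best_transcript_pairing(chains_a, chains_b)
    out = os.path.join(out_dir, "concordance.tsv")
    with open(out, "wt") as fh:
        fh.write(
            "transcript_a\ttranscript_b\tbase_jaccard\texact_exon_matches\t"
            "a_only\tb_only\tidentical\n"
        )
        for ta, tb, conc in pairs:
            fh.write(
                f"{ta}\t{tb}\t{conc.base_jaccard:.6f}\t{conc.exact_exon_matches}\t"
                f"{conc.a_only}\t{conc.b_only}\t{str(conc.identical).lower()}\n"
            )
    report.append(
        "concord: "
        + "; ".join(
            f"{ta}~{tb} jaccard={c.base_jaccard:.3f} identical={c.identical}"
            for ta, tb, c in pairs
        )
    )


def _stage_gc_pcr(cfg: Mapping[str, str], out_dir: str, report: list[str]) -> None:
    templates = read_fasta(cfg["template_fasta"])
    pairs = _parse_primer_pairs(cfg["primers"])
    window = int(cfg.get("gc_window", "100"))
    step = int(cfg.get("gc_step", "100"))
    with open(os.path.join(out_dir, "amplicons.tsv"), "wt") as amp, open(
        os.path.join(out_dir, "gc.tsv"), "wt"
    ) as gct:
        amp.write(
            "template_id\tpair\tforward_start\tforward_end\treverse_start\t"
            "reverse_end\tproduct_length\tproduct_gc\n"
        )
        gct.write("template_id\tglobal_gc\twindow_start\twindow_gc\n")
        for tid in sorted(templates):
            seq = templates[tid]
            global_gc = gc_content(seq)
            for start, gc in gc_sliding(seq, min(window, len(seq)), step):
                gct.write(f"{tid}\t{global_gc:.2f}\t{start}\t{gc:.2f}\n")
            for pair in pairs:
                for a in insilico_pcr(seq, pair, template_id=tid):
                    amp.write(
                        f"{tid}\t{pair.name}\t{a.forward_site[0]}\t{a.forward_site[1]}"
                        f"\t{a.reverse_site[0]}\t{a.reverse_site[1]}\t"
                        f"{a.product_length}\t{a.product_gc:.2f}\n"
                    )
                    report.append(
                        f"pcr: {tid} {pair.name} product {a.product_length} bp "
                        f"({a.product_gc:.2f}% GC)"
                    )
            report.append(f"gc: {tid} global GC {global_gc:.2f}%")
    program = slowdown_program(
        anneal_start=float(cfg.get("anneal_start", "72")),
        anneal_end=float(cfg.get("anneal_end", "65")),
        decrement=float(cfg.get("decrement", "1")),
        cycles_per_block=int(cfg.get("cycles_per_block", "4")),
    )
    with open(os.path.join(out_dir, "program.txt"), "wt") as fh:
        fh.write(program.as_text() + "\n")
    report.append(
        f"slowdown: {len(program.blocks)} blocks, {program.total_cycles} cycles"
    )


def _stage_exonmap(cfg: Mapping[str, str], out_dir: str, report: list[str]) -> None:
    queries = read_fasta(cfg["query_fasta"])
    ref = read_fasta(cfg["reference_exons_fasta"])
    ref_exons = [ref[k] for k in sorted(ref)]
    with open(os.path.join(out_dir, "splicedmap.tsv"), "wt") as fh:
        fh.write(
            "query_id\texon_index\tmatched\tidentity\tquery_start\tquery_end\n"
        )
        for qid in sorted(queries):
            smap = map_exons(queries[qid], ref_exons, query_id=qid)
            for rec in smap.exon_records:
                span = rec.query_span or (".", ".")
                fh.write(
                    f"{qid}\t{rec.exon_index}\t{str(rec.matched).lower()}\t"
                    f"{rec.identity:.4f}\t{span[0]}\t{span[1]}\n"
                )
            sig = signature(smap)
            report.append(
                f"exonmap: {qid} signature {sig.as_string()} "
                f"({smap.n_query_exons} exon(s) present; missing 5'->3' "
                f"{list(smap.missing_exons) or 'none'}, from 3' end "
                f"{list(smap.missing_exons_from_3p) or 'none'})"
            )


_STAGES = (
    ("localize", _stage_localize),
    ("classify", _stage_classify),
    ("concord", _stage_concord),
    ("gc_pcr", _stage_gc_pcr),
    ("exonmap", _stage_exonmap),
)


def run_all(config: RunConfig) -> list[str]:
    """Run every configured stage; returns the human-readable report lines.

    A stage failure raises :class:`StageError` naming the stage; outputs of
    earlier stages are retained.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report: list[str] = [
        f"syntenylocus {__version__} (python {sys.version.split()[0]})",
        f"seed: {config.seed}",
    ]
    for name, kv in config.sections.items():
        report.append(f"config [{name}]: " + " ".join(f"{k}={v}" for k, v in kv.items()))
    for name, fn in _STAGES:
        if name not in config.sections:
            continue
        try:
            fn(config.sections[name], config.out_dir, report)
        except Exception as exc:
            report.append(f"FAILED at stage {name}: {exc}")
            _write_log(config, report)
            raise StageError(name, str(exc)) from exc
    _write_log(config, report)
    return report


def _write_log(config: RunConfig, report: list[str]) -> None:
    with open(os.path.join(config.out_dir, "run.log"), "wt") as fh:
        fh.write("\n".join(report) + "\n")
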