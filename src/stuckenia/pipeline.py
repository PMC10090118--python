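"""End-to-end orchestration of the barcode identification analysis.

Stage order: read sequences (and optional metadata) -> align internally or
import an external alignment -> p-distance and TN93 matrices -> NJ tree
with bootstrap supports -> difference profiling against the reference
haplotype -> species classification -> group partitioning -> discordance
report -> summary.  Every artifact is a plain text file; re-running with
the same configuration and seed reproduces every analysis output
bit-for-bit (run.log carries wall-clock timings and is exempt).
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .genotyping import (
    DiagnosticKey,
    UNRESOLVED,
    ambiguity_profile,
    classify_sample,
    discordance_report,
    extract_diff_events,
    partition_groups,
)
from .msa import ScoringScheme, progressive_msa, read_alignment
from .phylo import bootstrap_support, p_distance_matrix, tn93_distance_matrix, write_newick
from .seqio import SampleTable, read_fasta, read_metadata


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run; echoed verbatim into run.log."""

    fasta: Union[str, Path]
    key: Union[str, Path]
    outdir: Union[str, Path]
    metadata: Optional[Union[str, Path]] = None
    aligned: Optional[Union[str, Path]] = None  # external alignment bypass
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    deletion: str = "pairwise"
    bootstrap_replicates: int = 1000
    seed: int = 42
    support_threshold: float = 50.0
    polymorphic_threshold: float = 0.005

    def validate(self) -> None:
        for name in ("fasta", "key", "metadata", "aligned"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name}={p} does not exist")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the populated run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"stuckenia-its {__version__} (python {platform.python_version()}, "
        f"numpy {np.__version__})",
        f"config: {config}",
        f"seed: {config.seed}",
    ]
    timings = []
    t_all = time.perf_counter()

    def stage(name):
        timings.append([name, time.perf_counter()])

    def stage_done():
        timings[-1][1] = time.perf_counter() - timings[-1][1]

    try:
        stage("read")
        records = read_fasta(config.fasta)
        metadata: Optional[SampleTable] = (
            read_metadata(config.metadata) if config.metadata else None
        )
        key = DiagnosticKey.from_yaml(config.key)
        sample_ids = [r.id for r in records]
        stage_done()

        stage("align")
        refs = key.reference_records()
        if config.aligned:
            aln = read_alignment(config.aligned)
            missing = (set(sample_ids) | {key.reference_id}) - set(aln.ids)
            if missing:
                raise ValueError(
                    f"external alignment lacks rows {sorted(missing)}"
                )
        else:
            ref_ids = {r.id for r in refs}
            overlap = ref_ids & set(sample_ids)
            if overlap:
                raise ValueError(
                    f"sample ids collide with key reference ids: {sorted(overlap)}"
                )
            aln = progressive_msa(records + refs, config.scheme)
        aln.to_fasta(outdir / "alignment.fasta")
        stage_done()

        stage("distances")
        pdm = p_distance_matrix(aln, config.deletion)
        pdm.to_csv(outdir / "distances.csv")
        tdm = tn93_distance_matrix(aln, config.deletion)
        tdm.to_csv(outdir / "distances_tn93.csv")
        if tdm.flags:
            log_lines.append(f"tn93 flagged pairs: {tdm.flags}")
        stage_done()

        stage("tree")
        tree = bootstrap_support(
            aln,
            replicates=config.bootstrap_replicates,
            seed=config.seed,
            deletion=config.deletion,
        )
        write_newick(tree, outdir / "tree.nwk", config.support_threshold)
        stage_done()

        stage("diff_profile")
        ev_rows = []
        for sid in sample_ids:
            pair = aln.pair(key.reference_id, sid)
            for ev in extract_diff_events(pair):
                ev_rows.append(
                    {
                        "sample_id": sid,
                        "kind": ev.kind,
                        "column": ev.column,
                        "length": ev.length,
                        "reference_run": ev.states[0],
                        "sample_run": ev.states[1],
                    }
                )
        _write_tsv(
            pd.DataFrame(
                ev_rows,
                columns=[
                    "sample_id", "kind", "column", "length",
                    "reference_run", "sample_run",
                ],
            ),
            outdir / "events.tsv",
        )
        stage_done()

        stage("classify")
        calls = [
            classify_sample(sid, aln, key, config.polymorphic_threshold)
            for sid in sample_ids
        ]
        call_rows = []
        for c in calls:
            prof = ambiguity_profile(
                aln.degapped(c.sample_id), config.polymorphic_threshold
            )
            call_rows.append(
                {
                    "sample_id": c.sample_id,
                    "call": c.call,
                    "ambiguity_fraction": c.ambiguity_fraction,
                    "polymorphic": prof.flagged,
                    "evidence": "; ".join(
                        f"{n}={o}->{t}" for n, o, t in c.evidence
                    ),
                    "conflicts": "; ".join(c.conflicts),
                }
            )
        _write_tsv(pd.DataFrame(call_rows), outdir / "calls.tsv")
        stage_done()

        stage("groups")
        groups, unresolved = partition_groups(calls)
        group_rows = [
            {"sample_id": sid, "group": groups.get(sid, UNRESOLVED)}
            for sid in sample_ids
        ]
        _write_tsv(pd.DataFrame(group_rows), outdir / "groups.tsv")
        stage_done()

        stage("discordance")
        if metadata is not None:
            report, orphans = discordance_report(calls, metadata)
            _write_tsv(report, outdir / "discordance.tsv")
            if orphans:
                log_lines.append(f"metadata orphans (no sequence): {orphans}")
        stage_done()

        stage("summary")
        summary = summarize(outdir)
        (outdir / "summary.txt").write_text(summary, encoding="utf-8")
        stage_done()
    except PipelineError:
        raise
    except Exception as exc:
        failed = timings[-1][0] if timings else "setup"
        _flush_log(outdir, log_lines, timings, t_all, error=f"{failed}: {exc}")
        raise PipelineError(failed, str(exc)) from exc

    _flush_log(outdir, log_lines, timings, t_all)
    return outdir


def _flush_log(outdir, log_lines, timings, t_all, error=None):
    lines = list(log_lines)
    for name, dt in timings:
        lines.append(f"stage {name}: {dt:.3f}s")
    lines.append(f"total: {time.perf_counter() - t_all:.3f}s")
    if error:
        lines.append(f"ERROR at {error}")
    (Path(outdir) / "run.log").write_text("\n".join(lines) + "\n", encoding="utf-8")


def summarize(run_directory: Union[str, Path]) -> str:
    """Text summary of a completed (or partial) run directory."""
    run_directory = Path(run_directory)
    calls_path = run_directory / "calls.tsv"
    if not calls_path.exists():
        raise FileNotFoundError(
            f"{run_directory}: no calls.tsv -- not a completed run directory"
        )
    calls = pd.read_csv(calls_path, sep="\t").fillna("")
    lines = ["== species calls =="]
    for call, n in calls["call"].value_counts().sort_index().items():
        lines.append(f"  {call}: {n}")
    groups_path = run_directory / "groups.tsv"
    partial = False
    if groups_path.exists():
        groups = pd.read_csv(groups_path, sep="\t")
        lines.append("== tree groups ==")
        for g, n in groups["group"].value_counts().sort_index().items():
            lines.append(f"  {g}: {n}")
    else:
        partial = True
    hybrids = calls.loc[calls["call"].str.startswith("hybrid("), "sample_id"]
    lines.append("== hybrids ==")
    lines.append("  " + (", ".join(hybrids) if len(hybrids) else "none"))
    poly = calls.loc[calls["polymorphic"] == True, "sample_id"]  # noqa: E712
    lines.append("== flagged polymorphic ==")
    lines.append("  " + (", ".join(poly) if len(poly) else "none"))
    disc_path = run_directory / "discordance.tsv"
    if disc_path.exists():
        disc = pd.read_csv(disc_path, sep="\t")
        bad = disc.loc[disc["concordant"] == False, "sample_id"]  # noqa: E712
        lines.append("== morphology/molecule discordance ==")
        lines.append("  " + (", ".join(bad) if len(bad) else "none"))
    if partial:
        lines.insert(0, "PARTIAL SUMMARY: some stage outputs are missing")
    return "\n".join(lines) + "\n"
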