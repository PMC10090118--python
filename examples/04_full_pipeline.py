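"""One-command end-to-end run: fixture -> alignment -> tree -> calls.

Equivalent to the CLI's `stuckenia-its demo`.  All artifacts land in a
temporary run directory; the summary is printed.
"""

import tempfile
from pathlib import Path

from stuckenia import RunConfig, build_haplotype_panel, run_pipeline
from stuckenia.synthdata import simulate_study, write_fixture

with tempfile.TemporaryDirectory() as td:
    root = Path(td)
    panel = build_haplotype_panel(seed=1)
    samples, truth = simulate_study(panel, seed=1)
    fixture = write_fixture(panel, samples, truth, root / "fixture")
    run = run_pipeline(
        RunConfig(
            fasta=fixture / "samples.fasta",
            metadata=fixture / "metadata.tsv",
            key=fixture / "key.yaml",
            outdir=root / "run",
            bootstrap_replicates=200,
            seed=1,
        )
    )
    print("artifacts:", ", ".join(sorted(p.name for p in run.iterdir())))
    print()
    print((run / "summary.txt").read_text())
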