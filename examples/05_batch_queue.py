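"""Run a processing queue and demonstrate resume logic.

Writes two specimen scans named by the DATE_ALLELE_ZYGOSITY_SEX convention,
queues a crop + bin + compress pipeline for each, runs the queue twice —
the second pass with resume, which skips both jobs because the outputs
already exist with matching input hashes.
"""

import tempfile
from pathlib import Path

import numpy as np

from embryotk import JobSpec, phantom_gen, run_queue, write_nrrd

with tempfile.TemporaryDirectory() as d:
    root = Path(d)
    jobs = []
    for k, allele in enumerate(["Cbx4", "Eya4"]):
        ph = phantom_gen.make_embryo_phantom(
            phantom_gen.random_embryo_spec(seed=k, dims=(40, 40, 40)))
        src = root / f"2016010{k + 1}_{allele}_hom_XX.nrrd"
        write_nrrd(ph.volume.astype_tag("uint8"), src)
        jobs.append(JobSpec(
            input=src, output_root=root / "processed", centre="HAR",
            procedure="E14.5_microCT",
            steps=[{"kind": "crop", "padding": 4}, {"kind": "resize", "bin": 2},
                   {"kind": "compress"}]))

    report = run_queue(jobs)
    for r in report.results:
        rel = r.output.relative_to(root) if r.output else None
        print(f"{r.job.input.name}: {r.status} -> {rel}")

    again = run_queue(jobs, resume=True)
    print("resume pass:", [r.status for r in again.results])
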