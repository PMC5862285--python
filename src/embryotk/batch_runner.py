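"""Sequential batch processing: job queue, naming convention, resume logic.

A processing job reads one reconstruction (slice-stack directory or NRRD
file), applies an ordered list of steps (crop / resize / compress / convert)
and writes a standard NRRD into a hierarchical output layout
``<root>/<centre>/<procedure>/<allele>/``. Jobs run strictly in sequence —
queues are set up and left running overnight — and one failure never aborts
the queue. Outputs are written to a temporary file and atomically renamed, so
a failed or interrupted job leaves no partial file behind.

Already-processed detection: each output NRRD records a sha256 of its input
content in the header; with ``resume=True`` a job whose output exists with a
matching hash is reported as skipped.

Specimen filenames follow the convention
``DATE_ALLELE_ZYGOSITY_SEX[_EXTRA...]`` (e.g. ``20160101_Cbx4_hom_XX``) with
strict vocabularies for date (YYYYMMDD), zygosity (het/hom/wt) and sex
(XX/XY/ND); extra tokens are preserved opaquely.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import autocrop, resample, volume_io
from .errors import EmbryotkError, NamingViolationError
from .types import Volume3D

logger = logging.getLogger("embryotk.batch")

ZYGOSITIES = ("het", "hom", "wt")
SEXES = ("XX", "XY", "ND")
_STEP_KINDS = ("crop", "resize", "compress", "convert")


# ---------------------------------------------------------------------------
# specimen naming convention
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecimenName:
    date: str  # YYYYMMDD
    allele: str
    zygosity: str  # het | hom | wt
    sex: str  # XX | XY | ND
    extra: tuple[str, ...] = ()

    def format(self) -> str:
        return "_".join((self.date, self.allele, self.zygosity, self.sex)
                        + self.extra)


def parse_specimen_name(filename: str) -> SpecimenName:
    """Parse ``DATE_ALLELE_ZYGOSITY_SEX[_EXTRA...]`` with strict validation."""
    stem = Path(filename).name
    for suffix in (".nrrd", ".nhdr", ".tar", ".gz", ".bz2"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    tokens = stem.split("_")
    if len(tokens) < 4:
        raise NamingViolationError(
            f"{filename!r}: expected at least DATE_ALLELE_ZYGOSITY_SEX, "
            f"got {len(tokens)} token(s)")
    date, allele, zygosity, sex = tokens[:4]
    try:
        datetime.datetime.strptime(date, "%Y%m%d")
    except ValueError:
        raise NamingViolationError(
            f"{filename!r}: token {date!r} is not a YYYYMMDD date") from None
    if not allele:
        raise NamingViolationError(f"{filename!r}: empty allele token")
    if zygosity not in ZYGOSITIES:
        raise NamingViolationError(
            f"{filename!r}: token {zygosity!r} not a zygosity {ZYGOSITIES}")
    if sex not in SEXES:
        raise NamingViolationError(
            f"{filename!r}: token {sex!r} not a sex {SEXES}")
    return SpecimenName(date, allele, zygosity, sex, tuple(tokens[4:]))


# ---------------------------------------------------------------------------
# job specs
# ---------------------------------------------------------------------------

@dataclass
class JobSpec:
    """One queue entry: an input, an ordered step list, an output root."""

    input: Path
    steps: list[dict]
    output_root: Path
    centre: str = ""
    procedure: str = ""
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.input = Path(self.input)
        self.output_root = Path(self.output_root)
        if not self.steps:
            raise ValueError("steps must be non-empty")
        for step in self.steps:
            self._validate_step(step)

    @staticmethod
    def _validate_step(step: dict) -> None:
        kind = step.get("kind")
        if kind not in _STEP_KINDS:
            raise ValueError(f"unknown step kind {kind!r}; expected {_STEP_KINDS}")
        if kind == "crop":
            if "manual" in step:
                rect = str(step["manual"]).split(",")
                if len(rect) != 4:
                    raise ValueError(
                        f"manual crop must be 'y0,y1,x0,x1', got {step['manual']!r}")
                [int(v) for v in rect]
            padding = int(step.get("padding", autocrop.DEFAULT_PADDING))
            if padding < 0:
                raise ValueError("crop padding must be >= 0")
            clip = float(step.get("clip", autocrop.DEFAULT_CLIP_FRACTION))
            if not 0 <= clip < 0.5:
                raise ValueError("crop clip fraction must be in [0, 0.5)")
        elif kind == "resize":
            if "bin" in step:
                resample.ResamplePlan(mode="bin", factor=int(step["bin"]))
            elif "spacing" in step:
                resample.ResamplePlan(
                    mode="resample",
                    target_spacing=tuple(float(s) for s in step["spacing"]),
                    interpolation=step.get("interpolation", "linear"))
            else:
                raise ValueError("resize step needs 'bin' or 'spacing'")

    def output_path(self) -> Path:
        parts = [p for p in (self.centre, self.procedure) if p]
        try:
            allele = parse_specimen_name(self.input.name).allele
            parts.append(allele)
        except NamingViolationError:
            pass
        stem = self.input.stem if self.input.suffix else self.input.name
        return self.output_root.joinpath(*parts) / f"{stem}.nrrd"


def load_manifest(path: str | Path) -> list[JobSpec]:
    """Load a YAML job manifest: a list of {input, steps, output_root, ...}."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, list):
        raise ValueError(f"{path}: manifest must be a YAML list of jobs")
    jobs = []
    for entry in doc:
        jobs.append(JobSpec(
            input=entry["input"],
            steps=list(entry["steps"]),
            output_root=entry["output_root"],
            centre=entry.get("centre", ""),
            procedure=entry.get("procedure", ""),
            spacing=tuple(entry.get("spacing", (1.0, 1.0, 1.0))),
        ))
    return jobs


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

@dataclass
class JobResult:
    job: JobSpec
    status: str  # "ok" | "failed" | "skipped"
    output: Path | None = None
    reason: str = ""
    elapsed_s: float = 0.0


@dataclass
class RunReport:
    results: list[JobResult] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {"ok": 0, "failed": 0, "skipped": 0}
        for r in self.results:
            out[r.status] += 1
        return out

    def to_json(self) -> str:
        return json.dumps([
            {"input": str(r.job.input), "status": r.status,
             "output": str(r.output) if r.output else None,
             "reason": r.reason, "elapsed_s": round(r.elapsed_s, 3)}
            for r in self.results], indent=2)


def _hash_input(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for p in sorted(path.iterdir(), key=lambda q: q.name):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _read_input(job: JobSpec) -> Volume3D:
    if job.input.is_dir():
        return volume_io.read_slice_stack(job.input, spacing=job.spacing)
    return volume_io.read_nrrd(job.input)


def execute_job(job: JobSpec, input_hash: str) -> Path:
    """Run one job's steps and atomically write its output NRRD."""
    vol = _read_input(job)
    compress = False
    for step in job.steps:
        kind = step["kind"]
        if kind == "crop":
            padding = int(step.get("padding", autocrop.DEFAULT_PADDING))
            clip = float(step.get("clip", autocrop.DEFAULT_CLIP_FRACTION))
            if "manual" in step:
                rect = tuple(int(v) for v in str(step["manual"]).split(","))
                box = autocrop.manual_crop_box(rect, vol)
            else:
                box = autocrop.derive_crop_box(
                    vol, None, padding, bool(step.get("crop_z", False)), clip)
            vol = autocrop.apply_crop(vol, box)
        elif kind == "resize":
            if "bin" in step:
                vol = resample.bin_volume(vol, int(step["bin"]))
            else:
                vol = resample.resample_volume(
                    vol, tuple(float(s) for s in step["spacing"]),
                    step.get("interpolation", "linear"),
                    labels=bool(step.get("labels", False)))
        elif kind == "compress":
            compress = True
        # "convert" is implicit: output is always NRRD

    out_path = job.output_path()
    out_path.parent.mkdir(parents=True, exist_ok=True)
    vol.metadata["input_sha256"] = input_hash
    fd, tmp = tempfile.mkstemp(dir=out_path.parent, suffix=".nrrd.part")
    os.close(fd)
    try:
        volume_io.write_nrrd(vol, tmp, compress=compress)
        os.replace(tmp, out_path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
    return out_path


def _already_processed(job: JobSpec, input_hash: str) -> bool:
    out_path = job.output_path()
    if not out_path.exists():
        return False
    try:
        _, _, metadata, _ = volume_io.read_nrrd_array(out_path)
    except EmbryotkError:
        return False
    return metadata.get("input_sha256") == input_hash


def run_queue(jobs: list[JobSpec], resume: bool = False) -> RunReport:
    """Execute jobs strictly in order; failures are recorded, never fatal."""
    report = RunReport()
    for job in jobs:
        t0 = time.monotonic()
        try:
            if not job.input.exists():
                raise EmbryotkError(f"input {job.input} does not exist")
            input_hash = _hash_input(job.input)
            if resume and _already_processed(job, input_hash):
                logger.info("skipped (already processed): %s", job.input)
                report.results.append(JobResult(
                    job, "skipped", job.output_path(), "already processed",
                    time.monotonic() - t0))
                continue
            out = execute_job(job, input_hash)
        except (EmbryotkError, OSError, ValueError) as exc:
            logger.warning("job failed: %s: %s", job.input, exc)
            report.results.append(JobResult(
                job, "failed", None, str(exc), time.monotonic() - t0))
            continue
        logger.info("job ok: %s -> %s", job.input, out)
        report.results.append(JobResult(job, "ok", out, "",
                                        time.monotonic() - t0))
    return report
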