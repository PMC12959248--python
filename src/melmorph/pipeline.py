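"""End-to-end orchestration: masks -> morphometrics -> merged cohort -> report.

A run is described by a :class:`RunConfig` with exactly one input mode:

* ``masks`` — a directory of calibrated mask images plus a clinical cohort
  table; morphometrics are computed per mask and merged on ``case_id``;
* ``cohort`` — a cohort table that already carries the biomarker columns;
* ``synthetic`` — a generated cohort (and optional fixture masks).

Per-case failures while reading/measuring masks are logged and skipped (a
cohort analysis tolerates dropped cases); zero successfully processed cases
or a cohort/mask ID mismatch is fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .errors import MelmorphError, PipelineError
from . import mask_io, morphometry
from .synthetic import SyntheticCohortSpec, generate_cohort, DEFAULT_SEED
from .workflow import MelanomaSurvivalModel

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("melmorph")

MASK_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (one input mode only)."""

    mode: str = "synthetic"            # masks | cohort | synthetic
    mask_dir: str | None = None
    cohort_path: str | None = None
    out_dir: str = "melmorph_out"
    mpp_x: float | None = None
    mpp_y: float | None = None
    n_synthetic: int = 2000
    endpoints: tuple = ("os", "mss")
    bootstrap_reps: int = 0
    seed: int = DEFAULT_SEED
    alpha: float = 0.001
    age_as_binary: bool = False
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("masks", "cohort", "synthetic"):
            raise PipelineError(f"unknown input mode {self.mode!r}")
        if self.mode == "masks" and not (self.mask_dir and self.cohort_path):
            raise PipelineError("mask mode needs --mask-dir and --cohort")
        if self.mode == "cohort" and not self.cohort_path:
            raise PipelineError("cohort mode needs --cohort")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        bad = set(data) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        if "endpoints" in data:
            data["endpoints"] = tuple(data["endpoints"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def measure_mask_dir(mask_dir: str | Path, mpp_x: float | None,
                     mpp_y: float | None) -> tuple[list, list]:
    """Morphometrics for every mask image in a directory.

    Returns (records, skipped); each skip is a (filename, reason) pair.
    Calibration comes from sidecar ``<file>.json`` when present, else from
    the explicit arguments / TIFF tags.
    """
    mask_dir = Path(mask_dir)
    files = sorted(p for p in mask_dir.iterdir()
                   if p.suffix.lower() in MASK_SUFFIXES)
    if not files:
        raise PipelineError(f"no mask images found in {mask_dir}")
    records, skipped = [], []
    for path in files:
        try:
            mx, my = mpp_x, mpp_y
            sidecar = path.with_suffix(path.suffix + ".json")
            case_id = None
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
                mx = meta.get("mpp_x", mx)
                my = meta.get("mpp_y", my)
                case_id = meta.get("case_id")
            mask = mask_io.read_mask(path, mx, my, case_id=case_id)
            records.append(morphometry.compute_morphometrics(mask))
        except (MelmorphError, OSError) as e:
            log.warning("skipping %s: %s", path.name, e)
            skipped.append((path.name, str(e)))
    if not records:
        raise PipelineError("zero masks processed successfully")
    return records, skipped


def merge_cohort(morph: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Join morphometrics to the clinical table on case_id (fatal mismatch)."""
    morph = morph.rename(columns={"area_mm2": "area", "perimeter_mm": "perimeter",
                                  "major_mm": "major", "dbt_mm": "dbt"})
    missing = sorted(set(clinical["case_id"].astype(str))
                     - set(morph["case_id"].astype(str)))
    if missing:
        raise PipelineError(
            f"cohort cases without a processed mask: {missing[:20]}"
            + (" ..." if len(missing) > 20 else ""))
    return clinical.merge(
        morph[["case_id", "area", "perimeter", "major", "dbt", "ni"]],
        on="case_id", how="inner", validate="1:1")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a manifest of output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    import melmorph

    log.info("melmorph %s  config hash %s  seed %d",
             melmorph.__version__, config.config_hash(), config.seed)
    log.info("config: %s", json.dumps(asdict(config), default=str))

    skipped = []
    if config.mode == "synthetic":
        cohort, _truth = generate_cohort(
            SyntheticCohortSpec(n=config.n_synthetic, seed=config.seed))
        mask_io.write_cohort_table(cohort.round(6), out / "cohort_merged.csv")
    else:
        clinical = mask_io.read_cohort_table(config.cohort_path)
        if config.mode == "masks":
            records, skipped = measure_mask_dir(
                config.mask_dir, config.mpp_x, config.mpp_y)
            mask_io.write_morphometrics_table(records, out / "morphometrics.csv")
            morph = mask_io.read_morphometrics_table(out / "morphometrics.csv")
            cohort = merge_cohort(morph, clinical)
        else:
            cohort = clinical
        mask_io.write_cohort_table(cohort, out / "cohort_merged.csv")

    model = MelanomaSurvivalModel(
        cohort, endpoints=config.endpoints, alpha=config.alpha,
        age_as_binary=config.age_as_binary)
    results = model.fit(bootstrap_reps=config.bootstrap_reps, seed=config.seed)

    report = results.to_report()
    report["config_hash"] = config.config_hash()
    report["skipped_masks"] = skipped
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    figures = []
    if config.make_figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        for (param, ep) in results.km:
            ax = results.plot_km(param, ep)
            path = figdir / f"km_{param}_{ep}.png"
            ax.figure.savefig(path, dpi=110)
            plt.close(ax.figure)
            figures.append(str(path))
        if results.roc:
            ax = results.plot_roc()
            path = figdir / "roc_5yr.png"
            ax.figure.savefig(path, dpi=110)
            plt.close(ax.figure)
            figures.append(str(path))

    log.info("done: %d cox fits, %d skipped masks", len(results.cox), len(skipped))
    return {"report": str(out / "report.json"),
            "cohort": str(out / "cohort_merged.csv"),
            "figures": figures,
            "skipped_masks": skipped,
            "summary": results.summary()}
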