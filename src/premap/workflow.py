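"""End-to-end runs: config, staging, logging, report tables.

A run is a pure function of (config file, referenced inputs): stages read
peak tables and snapshots named in the sample manifest, execute the
analysis modules, and write one tabular text report per stage into the
output directory, together with a run log that echoes every parameter used
(no silent defaults) and a content hash per stage.  Re-running a completed
stage with unchanged inputs and parameters is a no-op.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .csp import DEFAULT_C_SCALE, csp_profile
from .md_distances import (
    CLOSE_HIGH_A,
    CLOSE_LOW_A,
    FAR_FLOOR_A,
    distance_series,
    read_snapshots,
)
from .peaklist_io import PeakTable, SampleMeta, read_peak_table
from .pre_core import DEFAULT_BLEACH_SNR, annotate_groups, build_pre_profile, delta_I
from .spre import (
    DDPHI_THRESHOLD,
    SIGMA_FRACTION,
    build_phi_profile,
    delta_phi,
    significance_filter,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the failing stage."""


@dataclass
class RunConfig:
    """Validated run configuration.

    ``samples`` maps sample names to (table path, metadata); ``stages``
    holds the stage wiring blocks; stage parameters default to the
    analysis-wide constants.
    """

    out_dir: Path
    samples: dict[str, tuple[Path, SampleMeta]] = field(default_factory=dict)
    snapshots: Path | None = None
    stages: dict = field(default_factory=dict)
    seed: int = 0
    bleach_snr_threshold: float = DEFAULT_BLEACH_SNR
    phi_convention: str = "results"
    ddphi_threshold: float = DDPHI_THRESHOLD
    sigma_fraction: float = SIGMA_FRACTION
    close_low_A: float = CLOSE_LOW_A
    close_high_A: float = CLOSE_HIGH_A
    far_floor_A: float = FAR_FLOOR_A
    csp_scale: float = DEFAULT_C_SCALE
    frame_interval_ns: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        samples = {}
        for name, block in doc.get("samples", {}).items():
            samples[name] = (resolve(block["path"]), SampleMeta.from_dict(block["meta"]))
        snapshots = doc.get("snapshots")
        cfg = cls(
            out_dir=resolve(doc["out_dir"]),
            samples=samples,
            snapshots=resolve(snapshots) if snapshots else None,
            stages=doc.get("stages", {}),
            seed=int(doc.get("seed", 0)),
            bleach_snr_threshold=float(doc.get("bleach_snr_threshold", DEFAULT_BLEACH_SNR)),
            phi_convention=doc.get("phi_convention", "results"),
            ddphi_threshold=float(doc.get("ddphi_threshold", DDPHI_THRESHOLD)),
            sigma_fraction=float(doc.get("sigma_fraction", SIGMA_FRACTION)),
            close_low_A=float(doc.get("close_low_A", CLOSE_LOW_A)),
            close_high_A=float(doc.get("close_high_A", CLOSE_HIGH_A)),
            far_floor_A=float(doc.get("far_floor_A", FAR_FLOOR_A)),
            csp_scale=float(doc.get("csp_scale", DEFAULT_C_SCALE)),
            frame_interval_ns=float(doc.get("frame_interval_ns", 1.0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = [str(p) for p, _ in self.samples.values() if not p.exists()]
        if self.snapshots is not None and not self.snapshots.exists():
            missing.append(str(self.snapshots))
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")
        if self.phi_convention not in ("results", "methods"):
            raise ValueError("phi_convention must be 'results' or 'methods'")

    def parameters(self) -> dict:
        """Every tunable actually used by the run, for the run log."""
        return {
            "seed": self.seed,
            "bleach_snr_threshold": self.bleach_snr_threshold,
            "phi_convention": self.phi_convention,
            "ddphi_threshold": self.ddphi_threshold,
            "sigma_fraction": self.sigma_fraction,
            "close_low_A": self.close_low_A,
            "close_high_A": self.close_high_A,
            "far_floor_A": self.far_floor_A,
            "csp_scale": self.csp_scale,
            "frame_interval_ns": self.frame_interval_ns,
        }


def _content_hash(cfg: RunConfig, stage: str, inputs: list[Path]) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(cfg.parameters(), sort_keys=True).encode())
    h.update(stage.encode())
    h.update(json.dumps(cfg.stages.get(stage, {}), sort_keys=True, default=str).encode())
    for p in sorted(set(map(str, inputs))):
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, log=sys.stderr) -> dict:
    """Execute all configured stages; return the run-log dict.

    Deterministic given config + referenced inputs; a stage whose inputs
    and parameters are unchanged since the previous run (content hash) is
    skipped.  Stage failures raise :class:`PipelineError` naming the stage,
    and the run log marks the run incomplete.
    """
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "runlog.json"
    prev = json.loads(log_path.read_text()) if log_path.exists() else {}
    runlog = {
        "premap_version": __version__,
        "python": sys.version.split()[0],
        "parameters": config.parameters(),
        "stages": {},
        "complete": False,
    }

    tables: dict[str, PeakTable] = {}

    def load(name: str) -> PeakTable:
        if name not in tables:
            if name not in config.samples:
                raise PipelineError(f"unknown sample {name!r}")
            path, meta = config.samples[name]
            tables[name] = read_peak_table(path, meta)
        return tables[name]

    def stage_inputs(names: list[str]) -> list[Path]:
        return [config.samples[n][0] for n in names if n in config.samples]

    def run_stage(stage: str, input_names: list[str], outputs: list[str], fn) -> None:
        paths = stage_inputs(input_names)
        if config.snapshots and stage == "distances":
            paths = paths + [config.snapshots]
        chash = _content_hash(config, stage, paths)
        done = prev.get("stages", {}).get(stage, {})
        if done.get("hash") == chash and all((out / f).exists() for f in outputs):
            print(f"[premap] {stage}: up to date, skipped", file=log)
            runlog["stages"][stage] = {**done, "skipped": True}
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - report failing stage by name
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        runlog["stages"][stage] = {"hash": chash, "outputs": outputs, "skipped": False}
        print(f"[premap] {stage}: wrote {', '.join(outputs)}", file=log)

    profiles = {}

    # --- PRE ratio profiles -------------------------------------------------
    for block in config.stages.get("pre_profiles", []):
        name = block["name"]
        fname = f"pre_profile_{name}.tsv"

        def _run(block=block, name=name, fname=fname):
            prof = build_pre_profile(
                load(block["dia"]), load(block["para"]), config.bleach_snr_threshold
            )
            prof = annotate_groups(prof)
            profiles[name] = prof
            _write_table(prof.df, out / fname)

        run_stage(f"pre_profile:{name}", [block["dia"], block["para"]], [fname], _run)

    # --- effector-difference profiles --------------------------------------
    for block in config.stages.get("delta_i", []):
        name = block["name"]
        fname = f"delta_i_{name}.tsv"

        def _run(block=block, fname=fname):
            di = delta_I(profiles[block["a"]], profiles[block["b"]])
            _write_table(di, out / fname)

        names = [
            b[k]
            for b in config.stages.get("pre_profiles", [])
            if b["name"] in (block["a"], block["b"])
            for k in ("dia", "para")
        ]
        run_stage(f"delta_i:{name}", names, [fname], _run)

    # --- solvent-PRE ϕ profiles ---------------------------------------------
    phi_profiles = {}
    for block in config.stages.get("spre_phi", []):
        name = block["name"]
        fname = f"phi_{name}.tsv"

        def _run(block=block, name=name, fname=fname):
            prof = build_phi_profile(
                load(block["dia"]),
                load(block["plus"]),
                load(block["minus"]),
                convention=config.phi_convention,
                bleach_snr_threshold=config.bleach_snr_threshold,
            )
            phi_profiles[name] = prof
            _write_table(prof.df, out / fname)

        run_stage(
            f"spre_phi:{name}",
            [block["dia"], block["plus"], block["minus"]],
            [fname],
            _run,
        )

    # --- significance filter -------------------------------------------------
    sig_block = config.stages.get("significance")
    if sig_block:
        outputs = ["significance.tsv", "significance_exclusions.tsv", "delta_phi_wt.tsv",
                   "delta_phi_mut.tsv"]

        def _run():
            wt65, wt75 = phi_profiles[sig_block["wt_65"]], phi_profiles[sig_block["wt_75"]]
            m65, m75 = phi_profiles[sig_block["mut_65"]], phi_profiles[sig_block["mut_75"]]
            records, excl = significance_filter(
                wt65, wt75, m65, m75, config.ddphi_threshold, config.sigma_fraction
            )
            _write_table(delta_phi(wt65, wt75), out / "delta_phi_wt.tsv")
            _write_table(delta_phi(m65, m75), out / "delta_phi_mut.tsv")
            _write_table(records, out / "significance.tsv")
            _write_table(excl, out / "significance_exclusions.tsv")

        names = [
            b[k]
            for b in config.stages.get("spre_phi", [])
            for k in ("dia", "plus", "minus")
        ]
        run_stage("significance", names, outputs, _run)

    # --- chemical shift perturbation ----------------------------------------
    for block in config.stages.get("csp", []):
        name = block["name"]
        fname = f"csp_{name}.tsv"

        def _run(block=block, fname=fname):
            df = csp_profile(
                load(block["a"]), load(block["b"]), c_scale=config.csp_scale,
                cutoff_ppm=block.get("cutoff_ppm"),
            )
            _write_table(df, out / fname)

        run_stage(f"csp:{name}", [block["a"], block["b"]], [fname], _run)

    # --- distance census ------------------------------------------------------
    if config.snapshots is not None:
        outputs = ["distance_census.tsv", "distance_summary.json",
                   "distance_hist_inter.tsv", "distance_hist_intra.tsv"]

        def _run():
            from .md_distances import distance_histogram

            snaps = read_snapshots(config.snapshots, config.frame_interval_ns)
            census = distance_series(
                snaps,
                close_low=config.close_low_A,
                close_high=config.close_high_A,
                far_floor=config.far_floor_A,
            )
            _write_table(census.records, out / "distance_census.tsv")
            (out / "distance_summary.json").write_text(
                json.dumps(census.summary(), indent=1) + "\n"
            )
            for klass in ("inter", "intra"):
                _write_table(
                    distance_histogram(census, klass), out / f"distance_hist_{klass}.tsv"
                )

        run_stage("distances", [], outputs, _run)

    # --- bleach/exclusion audit ----------------------------------------------
    audit_rows = []
    for name, prof in profiles.items():
        sub = prof.df[prof.df["bleached"]]
        for r in sub.itertuples(index=False):
            audit_rows.append(
                {"stage": name, "residue_index": r.residue_index,
                 "methyl_id": r.methyl_id, "reason": "bleached"}
            )
    _write_table(
        pd.DataFrame(audit_rows, columns=["stage", "residue_index", "methyl_id", "reason"]),
        out / "bleach_audit.tsv",
    )

    runlog["complete"] = True
    log_path.write_text(json.dumps(runlog, indent=1, default=str) + "\n")
    return runlog
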