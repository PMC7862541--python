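"""End-to-end orchestration: work files -> binding free energies.

The pipeline mirrors the analysis of a bidirectional non-equilibrium
binding study: per-transition work integration, a maximum-likelihood
free-energy estimate per repeat, averaging over independent repeats,
sign assembly with the restraint correction under the declared
double-system/single-box convention, Boltzmann combination of binding
poses, consensus over force fields, and (when experimental references
are supplied) relative free energies and accuracy metrics.

Outputs are CSV/JSON files carrying a provenance record (config hash,
seeds, package version).  No stage mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import (
    BindingRecord,
    PoseEstimate,
    RestraintDefinition,
    assemble_binding,
    average_repeats,
    combine_poses,
    consensus,
    ddg_matrix,
    kj_to_kcal,
    metrics,
    restraint_correction,
)
from .io import read_dhdl_file, read_work_manifest
from .work import WorkSet, bootstrap_stderr, estimate, integrate_work

__all__ = ["RunConfig", "run_pipeline", "estimate_from_manifest"]


@dataclass
class RunConfig:
    """Validated run parameters; round-trips to/from YAML."""

    temperature: float = 300.15
    report_units: str = "kcal/mol"
    estimator: str = "cft-ml"
    convention: str = "dssb-unbinding"
    seed: int = 0
    n_boot: int = 200
    flip_hysteresis: float = 0.2
    unbind_distance: float = 1.5
    min_persistence: int = 50
    restraint: Optional[dict] = None  # RestraintDefinition kwargs, or None
    experimental_csv: Optional[str] = None
    pose_combination: str = "boltzmann"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.report_units not in ("kcal/mol", "kJ/mol"):
            raise ValueError(f"unknown report unit {self.report_units!r}")
        if self.estimator not in ("cft-ml", "jarzynski", "cgi"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.convention not in ("dssb-unbinding", "dssb-binding"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.restraint is not None:
            RestraintDefinition(**self.restraint)  # validate eagerly

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def estimate_from_manifest(manifest: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Integrate every transition file and estimate one free energy per
    (host, guest, forcefield, pose, repeat) group.

    Returns a frame with the transition free energy (kJ/mol), its
    bootstrap or analytic standard error, and sample counts.
    """
    rows = []
    keys = ["host", "guest", "forcefield", "pose", "repeat"]
    for group, sub in manifest.groupby(keys, sort=True):
        works = {"forward": [], "reverse": []}
        for _, rec in sub.iterrows():
            series = read_dhdl_file(rec["path"], direction=rec["direction"])
            works[rec["direction"]].append(integrate_work(series))
        if config.estimator != "jarzynski" and (
            not works["forward"] or not works["reverse"]
        ):
            raise ValueError(
                f"group {group}: bidirectional estimator {config.estimator!r} "
                "needs transitions in both directions"
            )
        ws = WorkSet(
            forward_works=np.array(works["forward"] or [np.nan]),
            reverse_works=np.array(works["reverse"] or [np.nan]),
            temperature=config.temperature,
        )
        est = estimate(ws, method=config.estimator)
        stderr = est.stderr
        if config.estimator == "cgi":
            stderr = bootstrap_stderr(
                "cgi", ws, n_boot=config.n_boot, seed=config.seed
            )
        rows.append(
            dict(
                zip(keys, group),
                dg_kj=est.dg,
                stderr_kj=stderr,
                n_forward=est.n_forward,
                n_reverse=est.n_reverse,
                method=est.method,
            )
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig, manifest_path: str | Path, out_dir: str | Path
) -> dict:
    """Run estimate -> repeats -> pose combination -> consensus ->
    (ddg, metrics); write all outputs under ``out_dir``.

    Returns a result bundle with the per-stage DataFrames and the paths
    written.  Raises with the failing stage named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_work_manifest(manifest_path)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    estimates = stage("estimate", estimate_from_manifest, manifest, config)

    dg_corr = 0.0
    if config.restraint is not None:
        dg_corr = stage(
            "restraint_correction",
            restraint_correction,
            RestraintDefinition(**config.restraint),
            config.temperature,
        )

    # average repeats within each pose, then assemble the binding sign
    pose_rows = []
    for (host, guest, ff, pose), sub in estimates.groupby(
        ["host", "guest", "forcefield", "pose"], sort=True
    ):
        mean_dg, sem, sem_ok = average_repeats(sub["dg_kj"].to_numpy())
        dg_bind = assemble_binding(mean_dg, dg_corr, convention=config.convention)
        pose_rows.append(
            dict(
                host=host,
                guest=guest,
                forcefield=ff,
                pose=pose,
                dg_kj=dg_bind,
                stderr_kj=sem if sem_ok else 0.0,
                n_repeats=len(sub),
                status="clean",
            )
        )
    poses_df = pd.DataFrame(pose_rows)

    # Boltzmann-combine poses per host/guest/forcefield
    bind_rows = []
    for (host, guest, ff), sub in poses_df.groupby(
        ["host", "guest", "forcefield"], sort=True
    ):
        pose_estimates = [
            PoseEstimate(
                pose=r.pose,
                dg=r.dg_kj,
                stderr=r.stderr_kj,
                n_repeats=int(r.n_repeats),
            )
            for r in sub.itertuples()
        ]
        combined = stage(
            "combine_poses",
            combine_poses,
            pose_estimates,
            config.temperature,
            method=config.pose_combination,
        )
        bind_rows.append(
            dict(
                host=host,
                guest=guest,
                forcefield=ff,
                dg_kcal=kj_to_kcal(combined.dg),
                stderr_kcal=kj_to_kcal(combined.stderr),
            )
        )
    bind_df = pd.DataFrame(bind_rows)

    # consensus over force fields
    cons_rows = []
    for (host, guest), sub in bind_df.groupby(["host", "guest"], sort=True):
        records = [
            BindingRecord(
                host=host,
                guest=guest,
                forcefield=r.forcefield,
                dg_bind=r.dg_kcal,
                stderr=r.stderr_kcal,
            )
            for r in sub.itertuples()
        ]
        c = stage("consensus", consensus, records)
        cons_rows.append(
            dict(host=host, guest=guest, dg_kcal=c.dg_bind, stderr_kcal=c.stderr)
        )
    cons_df = pd.DataFrame(cons_rows)

    result = {
        "estimates": estimates,
        "poses": poses_df,
        "bind": bind_df,
        "consensus": cons_df,
    }

    # relative free energies and metrics need experimental references
    if config.experimental_csv is not None:
        exp = pd.read_csv(config.experimental_csv)
        merged = cons_df.merge(exp, on=["host", "guest"], how="inner")
        ddg_rows = []
        for guest, sub in merged.groupby("guest", sort=True):
            if len(sub) < 2:
                continue
            records = [
                BindingRecord(
                    host=r.host,
                    guest=guest,
                    forcefield="consensus",
                    dg_bind=r.dg_kcal,
                    stderr=r.stderr_kcal,
                )
                for r in sub.itertuples()
            ]
            for hi, hj, ddg, err in ddg_matrix(records):
                ddg_rows.append(
                    dict(guest=guest, host_i=hi, host_j=hj, ddg_kcal=ddg, err_kcal=err)
                )
        result["ddg"] = pd.DataFrame(ddg_rows)
        if len(merged) >= 2:
            rep = stage(
                "metrics",
                metrics,
                merged["dg_kcal"].to_numpy(),
                merged["dg_exp_kcal"].to_numpy(),
                n_boot=config.n_boot,
                seed=config.seed,
            )
            result["metrics"] = rep

    provenance = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "neqbind_version": __version__,
        "config": asdict(config),
        "n_transitions": int(len(manifest)),
    }
    written = []
    for name in ("estimates", "poses", "bind", "consensus", "ddg"):
        if name in result and len(result[name]):
            df = result[name].copy()
            df["config_hash"] = config.config_hash
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            written.append(str(p))
    if "metrics" in result:
        rep = result["metrics"]
        mpath = out / "metrics.json"
        mpath.write_text(
            json.dumps(
                {
                    "aue_kcal": rep.aue,
                    "aue_err_kcal": rep.aue_err,
                    "pearson": rep.pearson if rep.pearson_defined else None,
                    "pearson_err": rep.pearson_err,
                    "n": rep.n,
                    "config_hash": config.config_hash,
                },
                indent=2,
            )
        )
        written.append(str(mpath))
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    written.append(str(out / "provenance.json"))
    result["written"] = written
    result["provenance"] = provenance
    return result
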