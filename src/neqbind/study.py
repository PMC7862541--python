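"""Write a complete synthetic study to disk.

Produces the on-disk inputs the pipeline consumes — per-transition
dH/dlambda files, a manifest CSV, an experimental reference CSV — with
a ground-truth record, so end-to-end runs can be validated against
closed-form expectations.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .binding import kj_to_kcal
from .constants import kt_kj
from .io import write_xvg
from .synthetic import WorkGenSpec, gen_gaussian_work

__all__ = ["simulate_study"]


def simulate_study(
    out_dir: str | Path,
    seed: int = 0,
    hosts: Sequence[str] = ("hostA", "hostB", "hostC"),
    guests: Sequence[str] = ("g1",),
    forcefields: Sequence[str] = ("ff1", "ff2"),
    poses: Sequence[str] = ("primary", "secondary"),
    n_repeats: int = 3,
    n_transitions: int = 30,
    sigma: float = 2.0,
    temperature: float = 300.15,
    n_lambda: int = 11,
) -> dict:
    """Generate a synthetic bidirectional study under ``out_dir``.

    For every (host, guest, forcefield, pose) a true unbinding
    transition free energy is drawn once; each of ``n_repeats`` repeats
    contributes ``n_transitions`` forward and reverse transitions whose
    integrated works follow the CFT-consistent Gaussian generator.
    Work files are written as constant dH/dlambda series whose
    trapezoidal integral equals the sampled work exactly.

    Returns a dict with the manifest path, experimental CSV path and
    the ground truth (per-pose transition free energies and the
    closed-form Boltzmann-combined binding free energies, kJ/mol).
    """
    out = Path(out_dir)
    (out / "dhdl").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    lam_f = np.linspace(0.0, 1.0, n_lambda)
    lam_r = lam_f[::-1]

    manifest_rows = ["host,guest,forcefield,pose,repeat,direction,path"]
    truth: dict = {"temperature": temperature, "poses": {}, "binding_kj": {}}
    kt = kt_kj(temperature)
    for host in hosts:
        for guest in guests:
            for ff in forcefields:
                pose_dgs = {}
                for pose in poses:
                    # true transition dG (unbinding direction, kJ/mol)
                    dg_true = float(np.round(rng.uniform(10.0, 30.0), 3))
                    pose_dgs[pose] = dg_true
                    truth["poses"][f"{host}/{guest}/{ff}/{pose}"] = dg_true
                    for rep in range(1, n_repeats + 1):
                        ws = gen_gaussian_work(
                            WorkGenSpec(
                                dg_true=dg_true,
                                sigma=sigma,
                                n_forward=n_transitions,
                                n_reverse=n_transitions,
                                temperature=temperature,
                                seed=int(rng.integers(0, 2**31 - 1)),
                            )
                        )
                        for t, w in enumerate(ws.forward_works):
                            p = out / "dhdl" / (
                                f"{host}_{guest}_{ff}_{pose}_r{rep}_f{t}.xvg"
                            )
                            write_xvg(p, lam_f, np.full(n_lambda, w))
                            manifest_rows.append(
                                f"{host},{guest},{ff},{pose},{rep},forward,"
                                f"dhdl/{p.name}"
                            )
                        for t, w in enumerate(ws.reverse_works):
                            # constant c over the 1->0 path integrates to -c
                            p = out / "dhdl" / (
                                f"{host}_{guest}_{ff}_{pose}_r{rep}_b{t}.xvg"
                            )
                            write_xvg(p, lam_r, np.full(n_lambda, -w))
                            manifest_rows.append(
                                f"{host},{guest},{ff},{pose},{rep},reverse,"
                                f"dhdl/{p.name}"
                            )
                # closed-form Boltzmann combination of the planted poses:
                # binding dG of a pose is -dG_transition (unbinding sign)
                binds = np.array([-dg for dg in pose_dgs.values()])
                x = -binds / kt
                dg_bind = -kt * (x.max() + np.log(np.exp(x - x.max()).sum()))
                truth["binding_kj"][f"{host}/{guest}/{ff}"] = float(dg_bind)

    manifest_path = out / "manifest.csv"
    manifest_path.write_text("\n".join(manifest_rows) + "\n")

    # experimental references: consensus truth across force fields + noise
    exp_rows = ["host,guest,dg_exp_kcal"]
    for host in hosts:
        for guest in guests:
            vals = [
                truth["binding_kj"][f"{host}/{guest}/{ff}"] for ff in forcefields
            ]
            dg_kcal = kj_to_kcal(float(np.mean(vals)))
            exp_rows.append(
                f"{host},{guest},{dg_kcal + float(rng.normal(0, 0.3)):.4f}"
            )
    exp_path = out / "experimental.csv"
    exp_path.write_text("\n".join(exp_rows) + "\n")

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {
        "manifest": str(manifest_path),
        "experimental": str(exp_path),
        "truth": truth,
        "truth_path": str(truth_path),
    }
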