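"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the real inputs —
work distributions consistent with the Crooks fluctuation theorem,
Gaussian coordinate ensembles with a prescribed covariance, pose
flip/unbind geometry traces, over-defined dihedral parameter files —
so the estimators, entropy machinery and linter can be validated
end-to-end without running molecular dynamics.

Every generator takes an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import beta as _beta
from .entropy import GeometrySeries, TrajectoryEnsemble
from .work import DhdlSeries, WorkSet

__all__ = [
    "WorkGenSpec",
    "EnsembleGenSpec",
    "PoseSeriesSpec",
    "DihedralVariantSpec",
    "gen_gaussian_work",
    "gen_gaussian_ensemble",
    "gen_pose_series",
    "gen_ff_fixture",
    "gen_dhdl_series",
]


@dataclass(frozen=True)
class WorkGenSpec:
    """Parameters of a CFT-consistent Gaussian work generator.

    For Gaussian work distributions of common variance sigma^2 the
    Crooks theorem fixes the means: forward works are centred at
    dG + beta sigma^2/2 and works measured along the reverse (1->0)
    transition at -dG + beta sigma^2/2 (the dissipation is symmetric).
    """

    dg_true: float
    sigma: float
    n_forward: int
    n_reverse: int
    temperature: float = 300.15
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_forward < 1 or self.n_reverse < 1:
            raise ValueError("need at least one sample per direction")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class EnsembleGenSpec:
    """Multivariate-normal coordinate ensemble with known covariance.

    ``covariance`` is a symmetric PSD matrix over the 3N Cartesian
    coordinates in nm^2; ``mean`` (atoms x 3, nm) defaults to the
    origin and should be a spread-out structure when the ensemble will
    be superposed.
    """

    covariance: np.ndarray
    masses: np.ndarray
    n_frames: int
    seed: int = 0
    mean: Optional[np.ndarray] = None

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=float)
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "masses", masses)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise ValueError("covariance must be square")
        if cov.shape[0] != 3 * masses.size:
            raise ValueError("covariance must span 3N coordinates")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.any(masses <= 0):
            raise ValueError("all masses must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        eigmin = float(np.linalg.eigvalsh(0.5 * (cov + cov.T)).min())
        if eigmin < -1e-10 * max(1.0, float(np.abs(cov).max())):
            raise ValueError("covariance is not positive semi-definite")
        if self.mean is not None:
            mean = np.asarray(self.mean, dtype=float)
            if mean.shape != (masses.size, 3):
                raise ValueError("mean must have shape (atoms, 3)")
            object.__setattr__(self, "mean", mean)


@dataclass(frozen=True)
class PoseSeriesSpec:
    """Synthetic orientation/distance trace with optional planted
    flip and unbind events."""

    n_frames: int
    flip_frame: Optional[int] = None
    unbind_frame: Optional[int] = None
    noise_sd: float = 0.0
    seed: int = 0
    baseline_distance: float = 0.4
    unbound_distance: float = 3.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        for name in ("flip_frame", "unbind_frame"):
            v = getattr(self, name)
            if v is not None and not 0 <= v < self.n_frames:
                raise ValueError(f"{name} out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_gaussian_work(spec: WorkGenSpec) -> WorkSet:
    """Draw a bidirectional work set satisfying the Crooks theorem.

    Forward works ~ N(dG + beta sigma^2/2, sigma^2); reverse works
    (measured along 1->0) ~ N(-dG + beta sigma^2/2, sigma^2).  The log
    ratio of the forward density to the negated-reverse density is then
    exactly beta (W - dG), the Crooks fluctuation theorem.
    """
    rng = np.random.default_rng(spec.seed)
    b = _beta(spec.temperature)
    dissip = 0.5 * b * spec.sigma**2
    fwd = rng.normal(spec.dg_true + dissip, spec.sigma, size=spec.n_forward)
    rev = rng.normal(-spec.dg_true + dissip, spec.sigma, size=spec.n_reverse)
    return WorkSet(forward_works=fwd, reverse_works=rev, temperature=spec.temperature)


def gen_gaussian_ensemble(spec: EnsembleGenSpec) -> TrajectoryEnsemble:
    """Sample i.i.d. multivariate-normal frames with the requested
    covariance (and optional mean structure).

    The ensemble is aligned by construction (no rigid-body motion is
    added), so it is marked superposed.
    """
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.masses.size
    # eigen-decomposition sampling tolerates PSD (rank-deficient) input
    eigvals, eigvecs = np.linalg.eigh(0.5 * (spec.covariance + spec.covariance.T))
    eigvals = np.clip(eigvals, 0.0, None)
    z = rng.standard_normal((spec.n_frames, eigvals.size))
    flat = z @ (eigvecs * np.sqrt(eigvals)).T
    coords = flat.reshape(spec.n_frames, n_atoms, 3)
    if spec.mean is not None:
        coords = coords + spec.mean[None, :, :]
    return TrajectoryEnsemble(
        coordinates=coords,
        masses=spec.masses.copy(),
        label="synthetic-gaussian",
        superposed=True,
    )


def gen_pose_series(spec: PoseSeriesSpec) -> GeometrySeries:
    """Orientation-cosine and COM-distance trace with planted events.

    The cosine starts near +1 (primary orientation) and switches to
    near -1 at ``flip_frame``; the distance jumps from the bound
    baseline to an unbound value at ``unbind_frame``.  Gaussian noise
    of ``noise_sd`` is added to both series (dimensionless for the
    cosine, nm for the distance); the cosine is clipped to [-1, 1].
    """
    rng = np.random.default_rng(spec.seed)
    cos = np.full(spec.n_frames, 0.95)
    if spec.flip_frame is not None:
        cos[spec.flip_frame:] = -0.95
    dist = np.full(spec.n_frames, spec.baseline_distance)
    if spec.unbind_frame is not None:
        dist[spec.unbind_frame:] = spec.unbound_distance
    if spec.noise_sd > 0:
        cos = cos + rng.normal(0.0, spec.noise_sd, size=spec.n_frames)
        dist = dist + rng.normal(0.0, spec.noise_sd, size=spec.n_frames)
    cos = np.clip(cos, -1.0, 1.0)
    dist = np.clip(dist, 0.0, None)
    return GeometrySeries(com_distance=dist, orientation_cos=cos)


@dataclass(frozen=True)
class DihedralVariantSpec:
    """One over-defined dihedral group to inject into a parameter file.

    ``quadruple`` is the atom-type quadruple (wildcards are rejected:
    the pathology under test is atom-type specific); ``barriers`` are
    the distinct kcal/mol force constants of the variants, all sharing
    ``periodicity`` so the group satisfies the same-multiplicity rule.
    """

    quadruple: tuple[str, str, str, str]
    barriers: tuple[float, ...] = (0.16, 0.80)
    periodicity: int = 3
    phase: float = 0.0

    def __post_init__(self):
        if len(self.quadruple) != 4:
            raise ValueError("quadruple must have four atom types")
        if any(t.strip().upper() == "X" for t in self.quadruple):
            raise ValueError(
                "over-defined dihedral fixtures must be atom-type specific "
                "(no wildcard 'X' types)"
            )
        if len(self.barriers) < 2:
            raise ValueError("an over-defined group needs at least two variants")
        if len(set(self.barriers)) != len(self.barriers):
            raise ValueError("variant barriers must differ")
        if self.periodicity < 1:
            raise ValueError("periodicity must be >= 1")


_TYPE_POOL = [
    "c1", "c2", "ca", "cc", "cd", "ce", "cf", "cp", "cq", "cu",
    "cv", "cx", "cy", "n1", "n2", "n3", "n4", "na", "nb", "nc",
    "nd", "ne", "nf", "nh", "no", "o", "oh", "op", "oq", "p2",
    "p3", "p4", "p5", "s2", "s4", "s6", "sh", "ss", "sx", "sy",
]


def _fmt_amber_line(quad, divider, barrier, phase, periodicity) -> str:
    types = "-".join(f"{t:<2s}" for t in quad)
    return f"{types} {divider:4d} {barrier:10.5f} {phase:12.3f} {periodicity:12.1f}"


def gen_ff_fixture(
    n_clean: int,
    duplicates: Sequence[DihedralVariantSpec] = (),
    seed: int = 0,
) -> tuple[str, list[tuple[str, str, str, str]]]:
    """Emit an AMBER-style dihedral parameter block with injected
    over-defined groups, plus the ground-truth list of their
    direction-canonicalized quadruples.

    The block contains ``n_clean`` unique single-variant entries and,
    for each requested duplicate group, one entry per variant.  Variant
    entries of the same group are guaranteed to be separated by at
    least one unrelated line (the non-sequential placement that marks
    the real pathology).
    """
    if n_clean < 0:
        raise ValueError("n_clean must be non-negative")
    rng = np.random.default_rng(seed)
    dup_canon = set()
    for d in duplicates:
        fwd = tuple(d.quadruple)
        dup_canon.add(min(fwd, fwd[::-1]))

    # unique clean quadruples, distinct from the injected ones
    clean_quads: list[tuple[str, ...]] = []
    seen = set(dup_canon)
    while len(clean_quads) < n_clean:
        quad = tuple(rng.choice(_TYPE_POOL, size=4))
        canon = min(quad, quad[::-1])
        if canon in seen:
            continue
        seen.add(canon)
        clean_quads.append(quad)

    clean_lines = [
        _fmt_amber_line(
            q,
            1,
            float(np.round(rng.uniform(0.05, 2.0), 5)),
            float(rng.choice([0.0, 180.0])),
            int(rng.integers(1, 4)),
        )
        for q in clean_quads
    ]
    variant_lines: list[list[str]] = []  # one list of lines per duplicate group
    for d in duplicates:
        variant_lines.append(
            [
                _fmt_amber_line(d.quadruple, 1, barr, d.phase, d.periodicity)
                for barr in d.barriers
            ]
        )

    # Interleave: place variant lines at random distinct slots, then make
    # sure same-group variants are never adjacent by inserting clean lines
    # or spacer entries between them.
    lines: list[tuple[str, int]] = [(ln, -1) for ln in clean_lines]
    for gi, group in enumerate(variant_lines):
        for ln in group:
            lines.insert(int(rng.integers(0, len(lines) + 1)), (ln, gi))
    # enforce non-adjacency of same-group variants
    changed = True
    spacer_count = itertools.count()
    while changed:
        changed = False
        for i in range(len(lines) - 1):
            if lines[i][1] != -1 and lines[i][1] == lines[i + 1][1]:
                # insert a fresh unique spacer entry between them
                while True:
                    quad = tuple(rng.choice(_TYPE_POOL, size=4))
                    canon = min(quad, quad[::-1])
                    if canon not in seen:
                        seen.add(canon)
                        break
                spacer = _fmt_amber_line(
                    quad, 1, float(np.round(rng.uniform(0.05, 2.0), 5)), 0.0, 2
                )
                lines.insert(i + 1, (spacer, -1))
                next(spacer_count)
                changed = True
                break
    text = "\n".join(ln for ln, _ in lines) + "\n"
    return text, sorted(dup_canon)


def gen_dhdl_series(
    coefficients: Sequence[float],
    n_points: int,
    direction: str = "forward",
) -> tuple[DhdlSeries, float]:
    """Polynomial dH/dlambda on an even lambda grid, with the analytic
    work integral as ground truth.

    ``coefficients`` are in ascending power order (numpy polynomial
    convention).  The analytic integral is over the series' own path:
    0->1 for forward, 1->0 for reverse (negated).
    """
    if n_points < 2:
        raise ValueError("need at least 2 lambda points")
    poly = np.polynomial.Polynomial(list(coefficients))
    lam = np.linspace(0.0, 1.0, n_points)
    integral = float(poly.integ()(1.0) - poly.integ()(0.0))
    if direction == "reverse":
        lam = lam[::-1]
        integral = -integral
    series = DhdlSeries(
        lambda_values=lam, dhdl_values=poly(lam), direction=direction
    )
    return series, integral
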