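"""Conformational analysis of trajectory ensembles.

Schlitter's quasi-harmonic entropy, its contribution to the binding
free energy (holo minus apo), PCA free-energy surfaces over the leading
collective coordinates, rigid-body superposition, and detection of
pose-flip / unbinding events used to discard contaminated repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .constants import (
    AMU_KG,
    HBAR,
    KB_SI,
    KCAL_TO_J,
    NM_M,
    R_J_MOL_K,
    kt_kj,
)

__all__ = [
    "TrajectoryEnsemble",
    "GeometrySeries",
    "FESGrid",
    "PCAModel",
    "superpose",
    "schlitter_entropy",
    "entropy_contribution",
    "fit_pca",
    "project_fes",
    "filter_events",
    "EventVerdict",
]


@dataclass
class TrajectoryEnsemble:
    """Coordinate frames with per-atom masses.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in nm; ``masses``
    are in amu.  ``selection`` restricts every analysis to a subset of
    atoms (e.g. the heavy atoms of the unmodified sugar units shared by
    all hosts).  ``superposed`` records whether the frames have been
    rigid-body fitted; entropy refuses to run on unfitted ensembles
    unless the caller asserts alignment.
    """

    coordinates: np.ndarray
    masses: np.ndarray
    selection: Optional[np.ndarray] = None
    label: str = ""
    superposed: bool = False

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.masses.shape != (self.coordinates.shape[1],):
            raise ValueError("one mass per atom required")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if self.selection is None:
            self.selection = np.arange(self.coordinates.shape[1])
        else:
            self.selection = np.asarray(self.selection, dtype=int)
            if self.selection.size and (
                self.selection.min() < 0
                or self.selection.max() >= self.coordinates.shape[1]
            ):
                raise ValueError("selection index out of range")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def selected_coordinates(self) -> np.ndarray:
        """Selected coordinates flattened to (frames, 3 * n_selected)."""
        sub = self.coordinates[:, self.selection, :]
        return sub.reshape(self.n_frames, -1)


@dataclass(frozen=True)
class GeometrySeries:
    """Per-frame guest geometry: host-guest COM distance (nm) and the
    cosine of the guest orientation relative to the host axis."""

    com_distance: np.ndarray
    orientation_cos: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.com_distance, dtype=float)
        c = np.asarray(self.orientation_cos, dtype=float)
        object.__setattr__(self, "com_distance", d)
        object.__setattr__(self, "orientation_cos", c)
        if d.shape != c.shape or d.ndim != 1:
            raise ValueError("distance and cosine series must be equal-length 1-D")
        if d.size == 0:
            raise ValueError("empty geometry series")
        if np.any(d < 0):
            raise ValueError("COM distances must be non-negative")
        if np.any(np.abs(c) > 1.0 + 1e-6):
            raise ValueError("orientation cosine outside [-1, 1]")

    @property
    def n_frames(self) -> int:
        return self.com_distance.size


@dataclass(frozen=True)
class FESGrid:
    """2-D free-energy surface over the two leading principal
    components, in kcal/mol relative to the most populated bin."""

    pc1_edges: np.ndarray
    pc2_edges: np.ndarray
    free_energy: np.ndarray
    mask: np.ndarray  # True where the bin is empty (free energy undefined)

    def occupied_min(self) -> float:
        return float(self.free_energy[~self.mask].min())


@dataclass(frozen=True)
class PCAModel:
    """Principal components of the pooled Cartesian covariance."""

    mean: np.ndarray
    eigenvectors: np.ndarray  # columns, sorted by descending eigenvalue
    eigenvalues: np.ndarray
    n_selected: int

    def project(self, ensemble: TrajectoryEnsemble, n_components: int = 2) -> np.ndarray:
        x = ensemble.selected_coordinates()
        if x.shape[1] != self.mean.size:
            raise ValueError("ensemble selection does not match the PCA model")
        return (x - self.mean) @ self.eigenvectors[:, :n_components]


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation matrix and translation mapping mobile onto
    reference in the least-squares sense (proper rotation enforced)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if abs(np.linalg.det(u @ vt)) < 1e-12 or s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) selection: rotation ill-defined")
    dmat = np.diag([1.0, 1.0, d])
    rot = u @ dmat @ vt
    return rot, rc - mc @ rot


def superpose(
    ensemble: TrajectoryEnsemble, reference: np.ndarray
) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Rigid-body least-squares fit of every frame onto a reference.

    The optimal rotation/translation is computed over the ensemble's
    selection and applied to all atoms.  Returns the fitted ensemble
    (marked ``superposed``) and the per-frame RMSD (nm) to the
    reference over the selection.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (ensemble.n_atoms, 3):
        raise ValueError("reference must match the ensemble's atom count")
    sel = ensemble.selection
    ref_sel = ref[sel]
    out = np.empty_like(ensemble.coordinates)
    rmsd = np.empty(ensemble.n_frames)
    for i, frame in enumerate(ensemble.coordinates):
        rot, trans = _kabsch(frame[sel], ref_sel)
        out[i] = frame @ rot + trans
        diff = out[i][sel] - ref_sel
        rmsd[i] = np.sqrt((diff**2).sum() / sel.size)
    fitted = replace(ensemble, coordinates=out, superposed=True)
    return fitted, rmsd


def mean_structure_reference(
    ensembles: Sequence[TrajectoryEnsemble], n_iter: int = 2
) -> np.ndarray:
    """Iterated mean structure of pooled ensembles as a common fitting
    reference (fit to the running mean, recompute the mean, repeat)."""
    ref = np.concatenate([e.coordinates for e in ensembles]).mean(axis=0)
    for _ in range(n_iter):
        fitted = [superpose(e, ref)[0] for e in ensembles]
        ref = np.concatenate([e.coordinates for e in fitted]).mean(axis=0)
    return ref


def schlitter_entropy(
    ensemble: TrajectoryEnsemble,
    temperature: float,
    assume_superposed: bool = False,
) -> float:
    """Schlitter's upper-bound quasi-harmonic entropy, J/(mol K).

        S = (R/2) ln det[ 1 + (k_B T e^2 / hbar^2) M^{1/2} C M^{1/2} ]

    with C the covariance of the selected Cartesian coordinates about
    their mean and M the diagonal mass matrix.  Evaluated through the
    eigenvalues of the symmetrized mass-weighted covariance in SI units,
    where the determinant argument is dimensionless.  The identity term
    makes rank-deficient covariances (fewer frames than coordinates)
    well-defined; overall rigid-body motion must be removed first by
    :func:`superpose` (or asserted via ``assume_superposed`` for
    ensembles that are aligned by construction).
    """
    if ensemble.n_frames < 2:
        raise ValueError("entropy needs at least two frames")
    if not ensemble.superposed and not assume_superposed:
        raise ValueError(
            "ensemble not superposed; fit frames first or pass assume_superposed=True"
        )
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = ensemble.selected_coordinates() * NM_M  # (frames, 3n) in metres
    x = x - x.mean(axis=0)
    masses_kg = np.repeat(ensemble.masses[ensemble.selection], 3) * AMU_KG
    sqrt_m = np.sqrt(masses_kg)
    # mass-weighted covariance M^{1/2} C M^{1/2}, units kg m^2
    y = x * sqrt_m
    cov = (y.T @ y) / (ensemble.n_frames - 1)
    cov = 0.5 * (cov + cov.T)
    eigvals = np.linalg.eigvalsh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    prefactor = KB_SI * temperature * np.e**2 / HBAR**2  # 1/(kg m^2)
    return float(0.5 * R_J_MOL_K * np.sum(np.log1p(prefactor * eigvals)))


def schlitter_entropy_from_covariance(
    covariance_nm2: np.ndarray, masses_amu: np.ndarray, temperature: float
) -> float:
    """Closed-form Schlitter entropy of a known coordinate covariance.

    The analytic counterpart of :func:`schlitter_entropy` for a
    generating covariance (nm^2, over 3N Cartesian coordinates); used
    as the convergence oracle for sampled ensembles.
    """
    c = np.asarray(covariance_nm2, dtype=float) * NM_M**2
    masses_kg = np.repeat(np.asarray(masses_amu, dtype=float), 3) * AMU_KG
    sqrt_m = np.sqrt(masses_kg)
    d = sqrt_m[:, None] * c * sqrt_m[None, :]
    d = 0.5 * (d + d.T)
    eigvals = np.clip(np.linalg.eigvalsh(d), 0.0, None)
    prefactor = KB_SI * temperature * np.e**2 / HBAR**2
    return float(0.5 * R_J_MOL_K * np.sum(np.log1p(prefactor * eigvals)))


def entropy_contribution(s_holo: float, s_apo: float, temperature: float) -> float:
    """Conformational-entropy contribution to the binding free energy.

    Returns T (S_holo - S_apo) in kcal/mol (1 kcal = 4184 J).  The
    result is negative when the apo state is entropically richer, i.e.
    when binding is entropically penalized in favour of the unbound
    state.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return temperature * (s_holo - s_apo) / KCAL_TO_J


def fit_pca(ensembles: Sequence[TrajectoryEnsemble]) -> PCAModel:
    """Principal components of the pooled Cartesian covariance.

    All ensembles must share the same selection size and be superposed
    to a common reference.  The covariance is not mass-weighted (plain
    heavy-atom Cartesian PCA); eigenpairs are sorted by descending
    eigenvalue and each eigenvector's largest-magnitude component is
    made positive to fix the sign convention.
    """
    if not ensembles:
        raise ValueError("fit_pca needs at least one ensemble")
    xs = [e.selected_coordinates() for e in ensembles]
    width = {x.shape[1] for x in xs}
    if len(width) != 1:
        raise ValueError("ensembles differ in selection size")
    pooled = np.concatenate(xs)
    if pooled.shape[0] < 2:
        raise ValueError("pooled frame count must be at least 2")
    mean = pooled.mean(axis=0)
    centered = pooled - mean
    cov = (centered.T @ centered) / (pooled.shape[0] - 1)
    cov = 0.5 * (cov + cov.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for k in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] *= -1.0
    return PCAModel(
        mean=mean,
        eigenvectors=eigvecs,
        eigenvalues=np.clip(eigvals, 0.0, None),
        n_selected=width.pop() // 3,
    )


def project_fes(
    ensemble: TrajectoryEnsemble,
    model: PCAModel,
    temperature: float,
    bins: int = 80,
    keep_frames: Optional[np.ndarray] = None,
) -> FESGrid:
    """Free-energy surface over the two leading principal components.

    Frames are projected on PC1/PC2 and binned on a 2-D histogram; the
    free energy of a bin is -kT ln(count / max_count) converted to
    kcal/mol, so the most populated bin sits at exactly zero and empty
    bins are masked (undefined, not zero).  ``keep_frames`` optionally
    restricts the histogram to a boolean frame mask, e.g. the frames
    labelled bound by :func:`filter_events`.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    proj = model.project(ensemble, n_components=2)
    if keep_frames is not None:
        proj = proj[np.asarray(keep_frames, dtype=bool)]
    if proj.shape[0] == 0:
        raise ValueError("no frames left to histogram")
    counts, e1, e2 = np.histogram2d(proj[:, 0], proj[:, 1], bins=bins)
    mask = counts == 0
    kt_kcal = kt_kj(temperature) / 4.184
    fes = np.full_like(counts, np.nan)
    with np.errstate(divide="ignore"):
        fes[~mask] = -kt_kcal * np.log(counts[~mask] / counts.max())
    return FESGrid(pc1_edges=e1, pc2_edges=e2, free_energy=fes, mask=mask)


@dataclass(frozen=True)
class EventVerdict:
    """Outcome of pose-event filtering for one simulation repeat."""

    status: str  # clean | flipped | unbound
    frame: Optional[int] = None
    low_confidence: bool = False


def filter_events(
    series: GeometrySeries,
    flip_hysteresis: float = 0.2,
    unbind_distance: float = 1.5,
    min_persistence: int = 50,
) -> tuple[np.ndarray, EventVerdict]:
    """Label frames primary/secondary/unbound and judge the repeat.

    Orientation state follows the sign of the orientation cosine with
    hysteresis: a state change is committed only after ``|cos|`` exceeds
    ``flip_hysteresis`` on the new side for ``min_persistence``
    consecutive frames.  Frames with COM distance above
    ``unbind_distance`` (nm) for the same persistence are unbound.
    The repeat verdict is the first committed departure from the
    starting orientation: ``clean``, ``flipped(frame)`` or
    ``unbound(frame)`` with the frame index of the start of the
    persistent run.  A series that never exceeds the hysteresis band is
    judged with a low-confidence flag.  Deterministic and idempotent.
    """
    cos = series.orientation_cos
    dist = series.com_distance
    n = series.n_frames
    min_persistence = max(1, int(min_persistence))

    def instant_state(i: int, current: str) -> str:
        if dist[i] > unbind_distance:
            return "unbound"
        if cos[i] > flip_hysteresis:
            return "primary"
        if cos[i] < -flip_hysteresis:
            return "secondary"
        return current  # inside the hysteresis band: keep state

    decisive = (np.abs(cos) > flip_hysteresis) | (dist > unbind_distance)
    low_confidence = not bool(decisive.any())

    # initial state: first decisive frame's instantaneous state
    state = "primary"
    for i in range(n):
        s = instant_state(i, "primary")
        if decisive[i]:
            state = s
            break
    initial_state = state

    labels = np.empty(n, dtype=object)
    pending: Optional[str] = None
    pending_start = 0
    first_event: Optional[tuple[str, int]] = None
    for i in range(n):
        s = instant_state(i, state)
        if s == state:
            pending = None
        else:
            if s != pending:
                pending, pending_start = s, i
            if i - pending_start + 1 >= min_persistence:
                state = s
                labels[pending_start:i] = s  # relabel the committed run
                if first_event is None and s != initial_state:
                    first_event = (s, pending_start)
                pending = None
        labels[i] = state
    labels = labels.astype(str)

    if first_event is None:
        verdict = EventVerdict(status="clean", low_confidence=low_confidence)
    else:
        new_state, frame = first_event
        status = "unbound" if new_state == "unbound" else "flipped"
        verdict = EventVerdict(status=status, frame=frame, low_confidence=low_confidence)
    return labels, verdict
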